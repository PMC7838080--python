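"""Sequence similarity network construction, clustering and export.

Nodes are (representative) sequences; an undirected edge connects two
sequences whose local-alignment E-value passes the chosen cutoff.
Clusters are connected components — the usual practice when such
networks are viewed in Cytoscape — and function is transferred by
guilt-by-association: an uncharacterized query joining a cluster that
contains characterized members inherits their label as evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .pairwise_similarity import EDGE_COLUMNS, AlignmentResult

__all__ = [
    "SSNGraph",
    "ClusterAssignment",
    "QueryAssignment",
    "build_ssn",
    "connected_components",
    "threshold_sweep",
    "assign_query",
    "export_graph",
    "read_graph",
]


@dataclass
class SSNGraph:
    """A thresholded similarity network backed by :class:`networkx.Graph`.

    Node attributes: ``members`` (ids collapsed onto the representative,
    the representative included) and ``label`` (function annotation,
    empty string when uncharacterized).  Edge attributes: ``evalue``,
    ``identity``, ``bit_score``.
    """

    graph: nx.Graph
    evalue_cutoff: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def member_count(self, node: str) -> int:
        return len(self.graph.nodes[node].get("members", [node]))


@dataclass
class ClusterAssignment:
    """Partition of the node set into connected components.

    Cluster indices are deterministic: descending size, ties broken by
    the lexicographically smallest member id.
    """

    node_to_cluster: dict[str, int]
    clusters: list[set[str]]
    cluster_labels: list[dict[str, int]]  # multiset of function labels

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def build_ssn(
    alignments: Sequence[AlignmentResult],
    evalue_cutoff: float,
    singletons: Iterable[str] = (),
    labels: Mapping[str, str] | None = None,
    members: Mapping[str, Sequence[str]] | None = None,
) -> SSNGraph:
    """Build the network keeping edges with E-value <= cutoff.

    The node set is every id seen in any alignment plus explicitly
    registered ``singletons``; the graph is simple and undirected, with
    self-pairs ignored and the best (lowest) E-value kept for duplicate
    pairs.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue cutoff must be positive")
    labels = labels or {}
    members = members or {}
    g = nx.Graph()
    for aln in alignments:
        g.add_node(aln.query_id)
        g.add_node(aln.subject_id)
        if aln.query_id == aln.subject_id:
            continue
        if aln.evalue <= evalue_cutoff:
            prev = g.get_edge_data(aln.query_id, aln.subject_id)
            if prev is None or aln.evalue < prev["evalue"]:
                g.add_edge(
                    aln.query_id,
                    aln.subject_id,
                    evalue=aln.evalue,
                    identity=aln.identity,
                    bit_score=aln.bit_score,
                )
    for node in singletons:
        g.add_node(node)
    for node in g.nodes:
        g.nodes[node]["label"] = labels.get(node, "")
        g.nodes[node]["members"] = list(members.get(node, [node]))
    return SSNGraph(g, evalue_cutoff)


def connected_components(ssn: SSNGraph) -> ClusterAssignment:
    """Cluster by connected components with deterministic numbering."""
    comps = [set(c) for c in nx.connected_components(ssn.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    node_to_cluster = {n: i for i, c in enumerate(comps) for n in c}
    cluster_labels = []
    for comp in comps:
        counts: dict[str, int] = {}
        for n in comp:
            lab = ssn.graph.nodes[n].get("label", "")
            if lab:
                counts[lab] = counts.get(lab, 0) + 1
        cluster_labels.append(counts)
    return ClusterAssignment(node_to_cluster, comps, cluster_labels)


def threshold_sweep(
    alignments: Sequence[AlignmentResult],
    cutoffs: Sequence[float],
    singletons: Iterable[str] = (),
) -> pd.DataFrame:
    """Cluster statistics at each E-value cutoff.

    Returns one row per cutoff with columns cutoff, n_edges, n_clusters,
    largest_cluster_size.  Because loosening the cutoff can only add
    edges, n_clusters is non-increasing as the cutoff loosens.
    """
    rows = []
    singletons = list(singletons)
    for cutoff in cutoffs:
        ssn = build_ssn(alignments, cutoff, singletons=singletons)
        assign = connected_components(ssn)
        rows.append(
            {
                "cutoff": cutoff,
                "n_edges": ssn.n_edges,
                "n_clusters": assign.n_clusters,
                "largest_cluster_size": max((len(c) for c in assign.clusters), default=0),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class QueryAssignment:
    """Guilt-by-association report for one query attached to the network."""

    query_id: str
    status: str  # "clustered" | "unclustered"
    cluster_index: int | None
    cluster_size: int
    characterized_labels: dict[str, int]
    best_neighbor: str | None  # best-E-value characterized neighbor
    best_neighbor_evalue: float | None
    best_edge_evalue: float | None


def assign_query(
    ssn: SSNGraph,
    query_alignments: Sequence[AlignmentResult],
    cutoff: float | None = None,
) -> QueryAssignment:
    """Attach one query by its passing edges and report co-membership.

    ``query_alignments`` are alignments of a single query (absent from
    the graph) against graph nodes.  The report lists the labels of
    characterized enzymes in the joined cluster and the characterized
    neighbor with the best E-value; with no passing edge the verdict is
    "unclustered".
    """
    cutoff = ssn.evalue_cutoff if cutoff is None else cutoff
    qids = {a.query_id for a in query_alignments}
    if len(qids) != 1:
        raise ValueError("query_alignments must concern exactly one query")
    query = qids.pop()
    if query in ssn.graph:
        raise ValueError(f"query id {query!r} already present in the graph")
    passing = [
        a
        for a in query_alignments
        if a.evalue <= cutoff and a.subject_id in ssn.graph
    ]
    if not passing:
        return QueryAssignment(query, "unclustered", None, 0, {}, None, None, None)
    assign = connected_components(ssn)
    joined = sorted({assign.node_to_cluster[a.subject_id] for a in passing})
    # edges merge every touched component into one cluster
    nodes: set[str] = set()
    for ci in joined:
        nodes |= assign.clusters[ci]
    labels: dict[str, int] = {}
    for n in nodes:
        lab = ssn.graph.nodes[n].get("label", "")
        if lab:
            labels[lab] = labels.get(lab, 0) + 1
    best_char: tuple[float, str] | None = None
    for a in sorted(passing, key=lambda a: (a.evalue, a.subject_id)):
        if ssn.graph.nodes[a.subject_id].get("label", ""):
            best_char = (a.evalue, a.subject_id)
            break
    return QueryAssignment(
        query,
        "clustered",
        joined[0],
        len(nodes) + 1,
        labels,
        best_char[1] if best_char else None,
        best_char[0] if best_char else None,
        min(a.evalue for a in passing),
    )


def export_graph(ssn: SSNGraph, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML or a tab-separated edge list.

    GraphML carries node attributes (member_count, label) and edge
    attributes (evalue, pct_identity, bit_score) and round-trips through
    :func:`read_graph`.  The edge-TSV dialect shares its columns with
    the alignment table.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        g.graph["evalue_cutoff"] = ssn.evalue_cutoff
        for n, data in ssn.graph.nodes(data=True):
            g.add_node(
                n,
                label=data.get("label", ""),
                members=",".join(data.get("members", [n])),
                member_count=len(data.get("members", [n])),
            )
        for u, v, data in ssn.graph.edges(data=True):
            g.add_edge(
                u,
                v,
                evalue=float(data["evalue"]),
                pct_identity=round(100.0 * data.get("identity", 0.0), 4),
                bit_score=float(data.get("bit_score", 0.0)),
            )
        nx.write_graphml(g, path)
    elif format == "edge-tsv":
        rows = [
            {
                "query": min(u, v),
                "subject": max(u, v),
                "raw_score": "",
                "bit_score": round(float(d.get("bit_score", 0.0)), 2),
                "evalue": f"{float(d['evalue']):.3e}",
                "pct_identity": round(100.0 * d.get("identity", 0.0), 2),
                "aligned_columns": "",
            }
            for u, v, d in ssn.graph.edges(data=True)
        ]
        rows.sort(key=lambda r: (r["query"], r["subject"]))
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_graph(path: str | Path) -> SSNGraph:
    """Read a GraphML file written by :func:`export_graph`."""
    raw = nx.read_graphml(path)
    g = nx.Graph()
    for n, data in raw.nodes(data=True):
        members = data.get("members", n)
        g.add_node(
            n,
            label=data.get("label", ""),
            members=members.split(",") if members else [n],
        )
    for u, v, data in raw.edges(data=True):
        g.add_edge(
            u,
            v,
            evalue=float(data["evalue"]),
            identity=float(data.get("pct_identity", 0.0)) / 100.0,
            bit_score=float(data.get("bit_score", 0.0)),
        )
    return SSNGraph(g, float(raw.graph.get("evalue_cutoff", 0.0)))
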