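"""Distance matrices and neighbor-joining phylogeny with Newick output.

Distances derive from the package-wide global-identity convention:
p-distance (1 - identity) by default, with an optional Poisson
correction -ln(identity) for multiple hits.  Tree inference is the
Saitou–Nei neighbor-joining agglomeration, which recovers the generating
topology and branch lengths exactly whenever the input matrix is
additive.  Trees are :class:`skbio.TreeNode` objects, written as Newick
with six-decimal branch lengths.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .pairwise_similarity import AlignmentParams, global_align
from .seqio_motifs import ProteinRecord

__all__ = [
    "distances_from_identity",
    "nj_tree",
    "write_newick",
    "read_newick",
]

#: Distance assigned (with a warning) when Poisson correction meets
#: identity 0, where -ln(identity) diverges.
POISSON_CAP = 10.0


def distances_from_identity(
    records: Sequence[ProteinRecord],
    params: AlignmentParams = AlignmentParams(),
    model: str = "p",
    poisson_cap: float = POISSON_CAP,
) -> DistanceMatrix:
    """Pairwise distance matrix from global-alignment identities.

    ``model="p"`` gives the p-distance 1 - identity; ``model="poisson"``
    gives -ln(identity), capped at ``poisson_cap`` when identity is 0.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a distance matrix")
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    ids = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_align(records[i], records[j], params).identity
            if model == "p":
                dist = 1.0 - ident
            elif ident <= 0.0:
                warnings.warn(
                    f"identity 0 between {ids[i]} and {ids[j]}: Poisson "
                    f"distance capped at {poisson_cap}"
                )
                dist = poisson_cap
            else:
                dist = min(-np.log(ident), poisson_cap)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Agglomerates with the standard Q-criterion
    Q(i,j) = (n-2) d(i,j) - r(i) - r(j); ties break on the smallest
    (i, j) index pair.  Branch lengths use the two-point formulas;
    negative lengths are clamped to zero with a warning, the pre-clamp
    value kept on the node as ``pre_clamp_length``.  The returned tree
    is unrooted (trifurcating root) with the input taxa as leaves.
    """
    if isinstance(dm, np.ndarray):
        raise TypeError("pass a skbio DistanceMatrix (ids carry taxon names)")
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.asarray(dm.data, dtype=float).copy()
    if not np.allclose(d, d.T) or (d < 0).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    nodes: list[TreeNode] = [TreeNode(name=tid) for tid in dm.ids]
    clamped: list[tuple[str, float]] = []

    def _set_length(node: TreeNode, length: float) -> None:
        if length < 0:
            clamped.append((node.name or "<internal>", length))
            warnings.warn(
                f"negative NJ branch length {length:.6g} on "
                f"{node.name or 'internal node'} clamped to 0"
            )
            node.pre_clamp_length = length
            length = 0.0
        node.length = float(length)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # row-major: smallest (i, j)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        _set_length(nodes[i], li)
        _set_length(nodes[j], lj)
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final 3-taxon star: closed-form two-point lengths
    a, b, c = nodes
    root = TreeNode()
    _set_length(a, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    _set_length(b, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    _set_length(c, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    root.extend([a, b, c])
    root.clamped_branch_lengths = clamped
    return root


_NEEDS_QUOTE = set(" \t\n()[]':;,")


def _newick_label(name: str | None) -> str:
    if not name:
        return ""
    if set(name) & _NEEDS_QUOTE:
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        body = _newick_label(node.name)
    else:
        body = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
        body += _newick_label(node.name)
    if node.length is not None:
        body += f":{node.length:.6f}"
    return body


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize as Newick, branch lengths to six decimals, labels with
    special characters single-quoted.  Returns the string; writes it
    when ``path`` is given."""
    text = _newick_node(tree) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(path: str | Path) -> TreeNode:
    """Parse a Newick file into a :class:`skbio.TreeNode`.

    Malformed input raises a parse error carrying skbio's positional
    diagnostics.
    """
    return TreeNode.read(str(path), format="newick")
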