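"""Acyl-acceptor class prediction from network and pocket evidence.

Two independent evidence lines are combined.  Guilt-by-association: the
query is attached to the reference sequence similarity network and
inherits the acceptor-class labels of characterized enzymes in its
cluster.  Pocket electrostatics: the acceptor pocket of the
highest-identity template is mapped onto the query through a global
alignment and its net formal charge is classified — an acidic pocket
indicates a polyamine/amine acceptor, a basic pocket a shikimate-type
acceptor.  A non-indeterminate verdict requires an acidic or basic
mapped pocket and, unless pocket-only mode is chosen, agreeing cluster
evidence; any conflict between the two lines forces "indeterminate"
with both lines reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .pairwise_similarity import AlignmentParams, all_vs_all, local_align, global_align
from .seqio_motifs import MotifGateConfig, ProteinRecord, is_bahd_candidate, read_fasta
from .ssn_graph import QueryAssignment, SSNGraph, assign_query, build_ssn
from .structure_pocket import (
    ChargeModel,
    MappingError,
    PocketProfile,
    map_pocket_to_query,
)

__all__ = [
    "VERDICT_AMINE",
    "VERDICT_SHIKIMATE",
    "VERDICT_INDETERMINATE",
    "TemplateEntry",
    "ReferenceBundle",
    "PredictorConfig",
    "AcceptorPrediction",
    "predict_acceptor",
    "batch_predict",
]

VERDICT_AMINE = "polyamine/amine acceptor"
VERDICT_SHIKIMATE = "shikimate-type acceptor"
VERDICT_INDETERMINATE = "indeterminate"

_CLASS_FROM_POCKET = {"acidic": VERDICT_AMINE, "basic": VERDICT_SHIKIMATE}


@dataclass
class TemplateEntry:
    """A pocket-annotated template: its sequence and pocket profile.

    ``numbering`` maps pocket residue seqids to 0-based sequence
    positions when the template's numbering is not 1-based sequential.
    """

    record: ProteinRecord
    profile: PocketProfile
    numbering: Mapping[int, int] | None = None


@dataclass
class ReferenceBundle:
    """Characterized references: labeled sequences plus pocket templates."""

    records: list[ProteinRecord]
    labels: dict[str, str]  # record id -> acceptor-class label
    templates: list[TemplateEntry]
    params: AlignmentParams = field(default_factory=AlignmentParams)
    _ssn_cache: dict = field(default_factory=dict, repr=False)

    def ssn(self, evalue_cutoff: float) -> SSNGraph:
        if evalue_cutoff not in self._ssn_cache:
            alignments = all_vs_all(self.records, self.params, evalue_cutoff)
            self._ssn_cache[evalue_cutoff] = build_ssn(
                alignments,
                evalue_cutoff,
                singletons=[r.id for r in self.records],
                labels=self.labels,
            )
        return self._ssn_cache[evalue_cutoff]


@dataclass(frozen=True)
class PredictorConfig:
    evalue_cutoff: float = 10.0**-51.5
    identity_floor: float = 0.20
    use_cluster: bool = True
    use_pocket: bool = True
    require_motif_gate: bool = True
    override_motif_gate: bool = False
    gate: MotifGateConfig = MotifGateConfig()
    charge_model: ChargeModel = field(default_factory=ChargeModel)


@dataclass
class ClusterEvidence:
    status: str  # clustered | unclustered | disabled
    labels: dict[str, int] = field(default_factory=dict)
    best_neighbor: str | None = None
    best_neighbor_evalue: float | None = None

    @property
    def acceptor_class(self) -> str | None:
        classes = {lab for lab in self.labels}
        if len(classes) == 1:
            return next(iter(classes))
        return None  # no labels, or conflicting labels


@dataclass
class PocketEvidence:
    template_id: str | None
    net_charge: float | None
    electro_class: str | None
    n_unresolved: int = 0
    template_identity: float | None = None

    @property
    def acceptor_class(self) -> str | None:
        if self.electro_class is None:
            return None
        return _CLASS_FROM_POCKET.get(self.electro_class)


@dataclass
class AcceptorPrediction:
    query_id: str
    verdict: str
    cluster_evidence: ClusterEvidence
    pocket_evidence: PocketEvidence
    notes: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "query": self.query_id,
            "verdict": self.verdict,
            "cluster_status": self.cluster_evidence.status,
            "cluster_labels": ";".join(
                f"{k}×{v}" for k, v in sorted(self.cluster_evidence.labels.items())
            ),
            "best_neighbor": self.cluster_evidence.best_neighbor or "",
            "best_neighbor_evalue": (
                f"{self.cluster_evidence.best_neighbor_evalue:.3e}"
                if self.cluster_evidence.best_neighbor_evalue is not None
                else ""
            ),
            "pocket_template": self.pocket_evidence.template_id or "",
            "pocket_net_charge": (
                f"{self.pocket_evidence.net_charge:+.1f}"
                if self.pocket_evidence.net_charge is not None
                else ""
            ),
            "pocket_class": self.pocket_evidence.electro_class or "",
            "unresolved_pocket_positions": self.pocket_evidence.n_unresolved,
            "notes": "; ".join(self.notes),
        }


def _cluster_evidence(
    query: ProteinRecord, bundle: ReferenceBundle, config: PredictorConfig
) -> ClusterEvidence:
    ssn = bundle.ssn(config.evalue_cutoff)
    query_alignments = [
        local_align(query, ref, bundle.params) for ref in bundle.records
    ]
    qa: QueryAssignment = assign_query(ssn, query_alignments, config.evalue_cutoff)
    return ClusterEvidence(
        qa.status, qa.characterized_labels, qa.best_neighbor, qa.best_neighbor_evalue
    )


def _pocket_evidence(
    query: ProteinRecord, bundle: ReferenceBundle, config: PredictorConfig
) -> tuple[PocketEvidence, list[str]]:
    notes: list[str] = []
    if not bundle.templates:
        return PocketEvidence(None, None, None), ["no pocket templates in bundle"]
    scored = [
        (global_align(t.record, query, bundle.params).identity, t)
        for t in bundle.templates
    ]
    scored.sort(key=lambda x: (-x[0], x[1].record.id))
    identity, best = scored[0]
    try:
        profile, unresolved = map_pocket_to_query(
            best.record,
            best.profile,
            query,
            bundle.params,
            identity_floor=config.identity_floor,
            numbering=best.numbering,
            model=config.charge_model,
        )
    except MappingError as exc:
        notes.append(str(exc))
        return PocketEvidence(best.record.id, None, None, template_identity=identity), notes
    if unresolved:
        notes.append(
            f"{len(unresolved)} pocket position(s) unresolved in the "
            f"template-query alignment"
        )
    return (
        PocketEvidence(
            best.record.id,
            profile.net_charge,
            profile.electro_class,
            len(unresolved),
            identity,
        ),
        notes,
    )


def predict_acceptor(
    query: ProteinRecord,
    bundle: ReferenceBundle,
    config: PredictorConfig = PredictorConfig(),
) -> AcceptorPrediction:
    """Predict the acyl-acceptor class of one query.

    Deterministic for fixed inputs.  See the module docstring for how
    the two evidence lines combine into the verdict.
    """
    notes: list[str] = []
    if config.require_motif_gate:
        gate = is_bahd_candidate(query, config.gate)
        if not gate.accepted:
            if config.override_motif_gate:
                notes.append(f"motif gate overridden ({gate.rationale})")
            else:
                return AcceptorPrediction(
                    query.id,
                    VERDICT_INDETERMINATE,
                    ClusterEvidence("disabled"),
                    PocketEvidence(None, None, None),
                    [f"failed motif gate: {gate.rationale}"],
                )

    if config.use_cluster:
        cluster = _cluster_evidence(query, bundle, config)
    else:
        cluster = ClusterEvidence("disabled")
        notes.append("cluster evidence disabled (pocket-only mode): reduced confidence")

    if config.use_pocket:
        pocket, pocket_notes = _pocket_evidence(query, bundle, config)
        notes.extend(pocket_notes)
    else:
        pocket = PocketEvidence(None, None, None)
        notes.append("pocket evidence disabled (cluster-only mode): reduced confidence")

    pocket_class = pocket.acceptor_class
    cluster_class = cluster.acceptor_class

    if cluster.status == "unclustered" and pocket.electro_class is None:
        notes.append("insufficient homology: no passing network edge and no usable template")
        return AcceptorPrediction(query.id, VERDICT_INDETERMINATE, cluster, pocket, notes)

    # a class verdict always requires pocket support (acidic or basic)
    if pocket_class is None:
        if cluster_class is not None:
            notes.append(
                f"cluster evidence alone leans {cluster_class!r}; "
                f"no pocket corroboration, verdict stays indeterminate"
            )
        if pocket.electro_class == "neutral":
            notes.append("mapped pocket is electrostatically neutral")
        return AcceptorPrediction(query.id, VERDICT_INDETERMINATE, cluster, pocket, notes)

    if not config.use_cluster:
        return AcceptorPrediction(query.id, pocket_class, cluster, pocket, notes)

    if cluster_class == pocket_class:
        return AcceptorPrediction(query.id, pocket_class, cluster, pocket, notes)

    if cluster_class is None and cluster.labels:
        notes.append(
            "conflicting characterized labels in the joined cluster: "
            + ", ".join(sorted(cluster.labels))
        )
    elif cluster_class is None:
        notes.append(
            f"pocket evidence leans {pocket_class!r} but the query is "
            f"{cluster.status} with no characterized co-members"
        )
    else:
        notes.append(
            f"evidence conflict: cluster co-membership says {cluster_class!r}, "
            f"pocket charge says {pocket_class!r}"
        )
    return AcceptorPrediction(query.id, VERDICT_INDETERMINATE, cluster, pocket, notes)


def batch_predict(
    queries: Sequence[ProteinRecord] | str | Path,
    bundle: ReferenceBundle,
    out_tsv: str | Path | None = None,
    out_json: str | Path | None = None,
    config: PredictorConfig = PredictorConfig(),
) -> list[AcceptorPrediction]:
    """Predict every query in a FASTA file or record list.

    Writes a TSV row and a JSON object per query when output paths are
    given; indeterminate verdicts are reported, not raised.
    """
    if isinstance(queries, (str, Path)):
        queries = read_fasta(queries)
    if not queries:
        raise ValueError("no query records supplied")
    predictions = [predict_acceptor(q, bundle, config) for q in queries]
    if out_tsv is not None:
        pd.DataFrame([p.to_row() for p in predictions]).to_csv(
            out_tsv, sep="\t", index=False
        )
    if out_json is not None:
        payload = [
            {
                "query_id": p.query_id,
                "verdict": p.verdict,
                "cluster_evidence": asdict(p.cluster_evidence),
                "pocket_evidence": asdict(p.pocket_evidence),
                "notes": p.notes,
            }
            for p in predictions
        ]
        Path(out_json).write_text(json.dumps(payload, indent=2))
    return predictions
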