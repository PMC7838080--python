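"""Sequence I/O, conserved-motif scanning and redundancy collapsing.

BAHD acyltransferases carry two hallmark motifs: the catalytic HXXXD,
whose histidine acts as the general base near the middle of the chain,
and the structural DFGWG near the C terminus.  Family membership is
gated on finding both motifs in their expected positional windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ALPHABET",
    "CANONICAL_AA",
    "ProteinRecord",
    "MotifHit",
    "MotifGateConfig",
    "GateDecision",
    "RedundancyMap",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "scan_motifs",
    "is_bahd_candidate",
    "collapse_redundancy",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Residues outside the 20 canonical letters are folded onto X.  X never
#: satisfies a motif-anchor position.
ALPHABET = CANONICAL_AA + "X"

# ambiguity / rare codes accepted on input and mapped to X
_FOLD_TO_X = set("BZJUO")


class FastaError(ValueError):
    """Malformed FASTA input; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence; the atom of every sequence stage.

    ``source`` tags provenance: ``user`` input, ``bundled`` reference
    data, or ``synthetic`` generator output.
    """

    id: str
    sequence: str
    description: str = ""
    source: str = "user"

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue character(s) {sorted(bad)}"
            )
        if self.source not in ("user", "bundled", "synthetic"):
            raise ValueError(f"unknown source tag {self.source!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_residues(raw: str, line: int) -> str:
    out = []
    for ch in raw.upper():
        if ch in ALPHABET or ch == "*":  # stop handled at record level
            out.append(ch)
        elif ch in _FOLD_TO_X:
            out.append("X")
        else:
            raise FastaError(f"illegal residue character {ch!r}", line)
    return "".join(out)


def read_fasta(path: str | Path, source: str = "user") -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Sequences are uppercased, one terminal ``*`` stop is stripped, rare
    amino-acid codes (B, Z, J, U, O) fold to X, and duplicate ids are
    rejected.  Errors name the offending line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: tuple[str, str, int] | None = None  # id, description, line
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        rid, desc, hline = header
        seq = "".join(chunks)
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise FastaError(f"internal stop codon in record {rid!r}", hline)
        if not seq:
            raise FastaError(f"record {rid!r} has no sequence", hline)
        records.append(ProteinRecord(rid, seq, desc, source))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                chunks = []
                parts = line[1:].strip().split(None, 1)
                if not parts:
                    raise FastaError("empty FASTA header", lineno)
                rid = parts[0]
                if rid in seen:
                    raise FastaError(f"duplicate record id {rid!r}", lineno)
                seen.add(rid)
                header = (rid, parts[1] if len(parts) > 1 else "", lineno)
            else:
                if header is None:
                    raise FastaError("sequence data before first header", lineno)
                chunks.append(_normalize_residues(line.strip(), lineno))
    flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, sequence lines wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start`` is the 1-based position of the
    first motif residue."""

    motif_name: str  # "HXXXD" or "DFGWG"
    start: int
    matched: str
    mismatches: int = 0


_DFGWG = "DFGWG"
MOTIF_LENGTH = 5


def scan_motifs(record: ProteinRecord, max_dfgwg_mismatch: int = 1) -> list[MotifHit]:
    """Report every HXXXD and DFGWG occurrence, sorted by start position.

    HXXXD requires exact H and D anchors with any three middle residues;
    DFGWG tolerates up to ``max_dfgwg_mismatch`` substitutions (X counts
    as a mismatch at every position).
    """
    if max_dfgwg_mismatch not in (0, 1):
        raise ValueError("max_dfgwg_mismatch must be 0 or 1")
    seq = record.sequence
    hits: list[MotifHit] = []
    for i in range(len(seq) - MOTIF_LENGTH + 1):
        window = seq[i : i + MOTIF_LENGTH]
        if window[0] == "H" and window[4] == "D":
            hits.append(MotifHit("HXXXD", i + 1, window, 0))
        mm = sum(1 for a, b in zip(window, _DFGWG) if a != b)
        if mm <= max_dfgwg_mismatch:
            hits.append(MotifHit("DFGWG", i + 1, window, mm))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


@dataclass(frozen=True)
class MotifGateConfig:
    """Positional windows for the family-membership gate.

    The catalytic HXXXD must start within the central window (fractions
    of sequence length); DFGWG must start in the C-terminal portion.
    """

    hxxxd_window: tuple[float, float] = (0.25, 0.60)
    dfgwg_min_fraction: float = 2.0 / 3.0
    max_dfgwg_mismatch: int = 1


@dataclass(frozen=True)
class GateDecision:
    accepted: bool
    rationale: str
    hxxxd: MotifHit | None = None
    dfgwg: MotifHit | None = None

    def __bool__(self) -> bool:
        return self.accepted


def is_bahd_candidate(
    record: ProteinRecord, config: MotifGateConfig = MotifGateConfig()
) -> GateDecision:
    """Gate family membership on both conserved motifs.

    Accepts iff an HXXXD hit starts inside the central window and a
    DFGWG hit (within the configured mismatch budget) starts in the
    C-terminal portion of the chain.
    """
    n = len(record)
    hits = scan_motifs(record, config.max_dfgwg_mismatch)
    lo, hi = config.hxxxd_window
    hxxxd = next(
        (h for h in hits if h.motif_name == "HXXXD" and lo * n <= h.start <= hi * n),
        None,
    )
    dfgwg = next(
        (
            h
            for h in hits
            if h.motif_name == "DFGWG" and h.start >= config.dfgwg_min_fraction * n
        ),
        None,
    )
    failed = []
    if hxxxd is None:
        failed.append(
            f"no HXXXD motif within central window "
            f"[{lo:.0%}, {hi:.0%}] of sequence length"
        )
    if dfgwg is None:
        failed.append(
            f"no DFGWG motif (<= {config.max_dfgwg_mismatch} mismatch) in "
            f"C-terminal region (start >= {config.dfgwg_min_fraction:.0%})"
        )
    if failed:
        return GateDecision(False, "; ".join(failed), hxxxd, dfgwg)
    return GateDecision(
        True,
        f"HXXXD at {hxxxd.start} (H{hxxxd.start}), DFGWG-like "
        f"'{dfgwg.matched}' at {dfgwg.start}",
        hxxxd,
        dfgwg,
    )


@dataclass
class RedundancyMap:
    """representative id -> collapsed member ids (representative included)."""

    members: dict[str, list[str]]
    identity_threshold: float

    def representative_of(self, record_id: str) -> str:
        for rep, mem in self.members.items():
            if record_id in mem:
                return rep
        raise KeyError(record_id)


def collapse_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 1.0,
    params=None,
) -> tuple[RedundancyMap, list[ProteinRecord]]:
    """Greedy redundancy collapse in input order.

    At threshold 1.0 only exactly identical sequences collapse.  Below
    1.0 each record joins the first earlier representative whose global
    identity (terminal-overhang-trimmed) reaches the threshold, else
    starts a new group.  Deterministic for a fixed input order; the
    partition depends on that order, which is the documented behaviour
    of greedy clustering.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    members: dict[str, list[str]] = {}
    reps: list[ProteinRecord] = []
    if identity_threshold == 1.0:
        by_seq: dict[str, str] = {}
        for rec in records:
            rep = by_seq.get(rec.sequence)
            if rep is None:
                by_seq[rec.sequence] = rec.id
                members[rec.id] = [rec.id]
                reps.append(rec)
            else:
                members[rep].append(rec.id)
        return RedundancyMap(members, identity_threshold), reps

    from .pairwise_similarity import AlignmentParams, global_align

    params = params or AlignmentParams()
    for rec in records:
        placed = False
        for rep in reps:
            if global_align(rep, rec, params).identity >= identity_threshold:
                members[rep.id].append(rec.id)
                placed = True
                break
        if not placed:
            members[rec.id] = [rec.id]
            reps.append(rec)
    return RedundancyMap(members, identity_threshold), reps
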