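"""Synthetic protein families, toy structures and pocket variants.

Ground-truth fixtures for every pipeline stage without downloads: star
topology families diverged from independent random seed sequences that
all carry the two conserved motifs (HXXXD planted centrally, DFGWG near
the C terminus, mirroring their canonical positions in the real
enzymes), ideal α-helix CA traces for superposition tests, and pocket
charge-swap variants with an exactly known charge delta.

Substitution is uniform over the 19 alternative residues (not
matrix-weighted), which keeps the expected identity analytic:
E[identity to seed] = 1 - substitution_rate.  Motif anchors are
protected by default so that family divergence and the motif gate stay
independent experimental knobs.  Every operation is deterministic under
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio_motifs import CANONICAL_AA, MotifHit, ProteinRecord, scan_motifs
from .structure_pocket import Residue, Structure, _ONE_TO_THREE

__all__ = [
    "FamilySpec",
    "make_seed_sequence",
    "evolve_family",
    "make_family_set",
    "make_toy_structure",
    "make_scaffold_with_pocket",
    "make_pocket_variant",
]

_AA = np.array(list(CANONICAL_AA))


def _rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class FamilySpec:
    """Conditions for one simulated superfamily draw."""

    n_families: int = 2
    members_per_family: int = 5
    seed_length: int = 450
    substitution_rate: float = 0.1
    indel_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least 1 family and 1 member per family")
        if not 0.0 <= self.substitution_rate <= 0.95:
            raise ValueError("substitution_rate must be in [0, 0.95]")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel_rate must be in [0, 1)")


def motif_positions(length: int) -> tuple[int, int]:
    """1-based planted starts of HXXXD and DFGWG for a given length."""
    return round(0.35 * length), round(0.85 * length)


def make_seed_sequence(length: int, rng, record_id: str = "seed") -> ProteinRecord:
    """Uniform-random sequence with both family motifs planted.

    HXXXD starts at round(0.35 * length) and DFGWG at
    round(0.85 * length) (1-based), i.e. catalytic motif central,
    structural motif in the C-terminal region, as in the real family.
    """
    if length < 60:
        raise ValueError("seed length must be >= 60")
    rng = _rng(rng)
    seq = list(rng.choice(_AA, size=length))
    h_start, d_start = motif_positions(length)
    seq[h_start - 1] = "H"
    seq[h_start + 3] = "D"
    seq[d_start - 1 : d_start + 4] = list("DFGWG")
    return ProteinRecord(record_id, "".join(seq), "synthetic seed", "synthetic")


def _protected_sites(record: ProteinRecord) -> tuple[set[int], set[int]]:
    """(anchor sites, full motif spans), 0-based, from exact motif hits."""
    anchors: set[int] = set()
    spans: set[int] = set()
    for hit in scan_motifs(record, max_dfgwg_mismatch=0):
        i0 = hit.start - 1
        spans.update(range(i0, i0 + 5))
        if hit.motif_name == "HXXXD":
            anchors.update({i0, i0 + 4})
        else:
            anchors.update(range(i0, i0 + 5))
    return anchors, spans


def _substitute(aa: str, rng: np.random.Generator) -> str:
    choices = [c for c in CANONICAL_AA if c != aa]
    return choices[rng.integers(len(choices))]


def evolve_family(
    seed: ProteinRecord,
    n: int,
    substitution_rate: float,
    indel_rate: float = 0.0,
    rng=None,
    protect_motifs: bool = True,
    extra_protected: Sequence[int] = (),
) -> list[ProteinRecord]:
    """Evolve ``n`` members independently from one seed.

    Each site is substituted with probability ``substitution_rate`` to a
    uniformly chosen different residue; motif anchors (H/D of HXXXD, all
    of DFGWG) and any ``extra_protected`` 1-based sites are immune when
    protection is on.  Indels (geometric length, mean 2) are placed
    outside motif spans when ``indel_rate`` > 0.
    """
    rng = _rng(rng)
    anchors, spans = _protected_sites(seed) if protect_motifs else (set(), set())
    protected = anchors | {p - 1 for p in extra_protected}
    indel_forbidden = spans | protected
    members = []
    for k in range(n):
        seq = list(seed.sequence)
        for i in range(len(seq)):
            if i in protected:
                continue
            if rng.random() < substitution_rate:
                seq[i] = _substitute(seq[i], rng)
        if indel_rate > 0:
            out: list[str] = []
            i = 0
            while i < len(seq):
                if i not in indel_forbidden and rng.random() < indel_rate:
                    length = int(rng.geometric(0.5))
                    if rng.random() < 0.5:  # insertion before site i
                        out.extend(rng.choice(_AA, size=length))
                        out.append(seq[i])
                        i += 1
                    else:  # deletion, stopping at any protected site
                        j = i
                        while j < min(i + length, len(seq)) and j not in indel_forbidden:
                            j += 1
                        i = j
                else:
                    out.append(seq[i])
                    i += 1
            seq = out
        members.append(
            ProteinRecord(
                f"{seed.id}.m{k + 1}",
                "".join(seq),
                f"family={seed.id}",
                "synthetic",
            )
        )
    return members


def make_family_set(spec: FamilySpec) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Independent families plus an id -> family truth table."""
    rng = _rng(spec.rng_seed)
    records: list[ProteinRecord] = []
    truth: dict[str, str] = {}
    for f in range(spec.n_families):
        fam = f"fam{f + 1}"
        seed = make_seed_sequence(spec.seed_length, rng, record_id=fam)
        members = evolve_family(
            seed,
            spec.members_per_family,
            spec.substitution_rate,
            spec.indel_rate,
            rng,
        )
        for m in members:
            truth[m.id] = fam
        records.extend(members)
    return records, truth


# ideal polyalanine-style helix geometry for CA traces
HELIX_RISE = 1.5  # Å per residue
HELIX_RADIUS = 2.3  # Å
HELIX_TWIST = 100.0  # degrees per residue


def make_toy_structure(
    n_residues: int,
    sigma: float = 0.0,
    rigid_transform: bool = False,
    rng=None,
    sequence: str | None = None,
    chain_id: str = "A",
    name: str = "toy",
) -> Structure:
    """Ideal α-helix CA trace, optionally perturbed and/or rigidly moved.

    Residue i (0-based) sits at (r cos(100°·i), r sin(100°·i), 1.5·i)
    with r = 2.3 Å.  ``sigma`` adds isotropic Gaussian noise; with only
    a rigid transform applied the ground-truth superposed RMSD against
    the unmoved trace is 0.  Residue names follow ``sequence`` when
    given (poly-ALA otherwise), so the chain sequence is usable by the
    alignment-based operations.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    if sequence is not None and len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    rng = _rng(rng)
    i = np.arange(n_residues)
    theta = np.deg2rad(HELIX_TWIST) * i
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )
    if sigma > 0:
        coords = coords + rng.normal(0.0, sigma, size=coords.shape)
    if rigid_transform:
        # random proper rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        coords = coords @ q.T + rng.uniform(-20, 20, size=3)
    residues = []
    for k in range(n_residues):
        aa = sequence[k] if sequence else "A"
        residues.append(
            Residue(chain_id, k + 1, "", _ONE_TO_THREE.get(aa, "ALA"), {"CA": coords[k]})
        )
    return Structure(name, {chain_id: residues}, {}, [])


def make_scaffold_with_pocket(
    pocket: Sequence[tuple[int, str]],
    length: int,
    rng,
    record_id: str = "scaffold",
) -> ProteinRecord:
    """Seed sequence with prescribed residues written at pocket sites.

    ``pocket`` is a list of (1-based position, one-letter residue).
    Positions clashing with the planted motifs are rejected so the gate
    and the pocket stay independent.
    """
    rng = _rng(rng)
    rec = make_seed_sequence(length, rng, record_id=record_id)
    h_start, d_start = motif_positions(length)
    reserved = set(range(h_start, h_start + 5)) | set(range(d_start, d_start + 5))
    seq = list(rec.sequence)
    for pos, aa in pocket:
        if pos in reserved:
            raise ValueError(f"pocket position {pos} collides with a planted motif")
        if not 1 <= pos <= length:
            raise ValueError(f"pocket position {pos} outside sequence")
        seq[pos - 1] = aa.upper()
    return ProteinRecord(record_id, "".join(seq), rec.description, "synthetic")


_INT_CHARGE = {"D": -1, "E": -1, "K": 1, "R": 1}


def make_pocket_variant(
    record: ProteinRecord,
    pocket_positions: Sequence[int],
    delta: int,
    rng=None,
) -> ProteinRecord:
    """Mutate pocket sites to shift the integer net charge by ``delta``.

    Uses the minimal number of substitutions: acidic<->basic swaps move
    two units each, charged<->neutral substitutions one unit.  Histidine
    sites are left untouched (their fractional charge would break the
    exact integer arithmetic).  Non-pocket positions are never changed;
    an unreachable delta raises an error stating the maximum reachable.
    """
    rng = _rng(rng)
    if delta == 0:
        return record
    seq = list(record.sequence)
    sign = 1 if delta > 0 else -1
    # per usable site: the largest charge move available in the needed direction
    gains: list[tuple[int, int]] = []  # (gain magnitude, 0-based site)
    for pos in pocket_positions:
        aa = seq[pos - 1]
        if aa == "H":
            continue
        c = _INT_CHARGE.get(aa, 0)
        if c * sign > 0:
            continue  # already charged in the requested direction
        # opposite-charged sites can move 2 units, neutral sites 1
        gains.append((2 if c != 0 else 1, pos - 1))
    max_reachable = sum(g for g, _ in gains)
    need = abs(delta)
    if need > max_reachable:
        raise ValueError(
            f"charge delta {delta:+d} unreachable from this pocket; "
            f"maximum reachable is {sign * max_reachable:+d}"
        )
    gains.sort(key=lambda x: (-x[0], x[1]))
    chosen: list[tuple[int, int]] = []
    remaining = need
    for gain, site in gains:
        if remaining <= 0:
            break
        chosen.append((min(gain, remaining), site))
        remaining -= min(gain, remaining)
    basic = "KR"
    acidic = "DE"
    neutral = "ST"
    for gain, site in chosen:
        if sign > 0:
            if seq[site] in acidic:
                new = basic[rng.integers(2)] if gain == 2 else neutral[rng.integers(2)]
            else:  # neutral site, gain 1
                new = basic[rng.integers(2)]
        else:
            if seq[site] in basic:
                new = acidic[rng.integers(2)] if gain == 2 else neutral[rng.integers(2)]
            else:  # neutral site, gain 1
                new = acidic[rng.integers(2)]
        seq[site] = new
    return ProteinRecord(
        f"{record.id}_d{delta:+d}",
        "".join(seq),
        f"{record.description} pocket-variant delta={delta:+d}".strip(),
        "synthetic",
    )
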