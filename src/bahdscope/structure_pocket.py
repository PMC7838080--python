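"""Structure parsing, superposition and acyl-acceptor pocket profiling.

The acceptor-specificity signal exploited here is electrostatic: the
spermidine/polyamine-accepting acyltransferases line their acceptor
pocket with acidic residues, while the shikimate-accepting relatives
present a basic pocket.  This module reads PDB files (via gemmi),
superposes structures by the Kabsch algorithm over alignment-paired CA
atoms, extracts pocket residues around a bound ligand (or takes an
explicit residue list), scores the pocket's formal charge at neutral pH
and classifies it as acidic / basic / neutral, and maps a template's
pocket onto a homologous query sequence through a global alignment.

Charge model: D, E = -1; K, R = +1; H = +0.1 (a histidine is only
fractionally protonated at neutral pH); everything else 0.  A pocket is
"acidic" when the net charge is <= -1 and "basic" when >= +1.  These
thresholds are this package's declared operationalization of the
qualitative surface-electrostatics argument; waters never contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .pairwise_similarity import AlignmentParams, _aligner, global_align
from .seqio_motifs import ProteinRecord

__all__ = [
    "Residue",
    "Structure",
    "SuperpositionResult",
    "PocketPosition",
    "PocketProfile",
    "ChargeModel",
    "MappingError",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "ca_rmsd_by_alignment",
    "extract_pocket",
    "pocket_charge",
    "map_pocket_to_query",
    "parse_position",
    "load_reference_pockets",
]

_WATER_NAMES = {"HOH", "WAT", "DOD"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def three_to_one(res_name: str) -> str:
    return _THREE_TO_ONE.get(res_name.upper(), "X")


@dataclass
class Residue:
    chain_id: str
    seqid: int
    icode: str
    name: str  # three-letter residue / ligand code
    atoms: dict[str, np.ndarray]  # atom name -> xyz (Å)

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name)

    def heavy_coords(self) -> np.ndarray:
        coords = [
            xyz
            for nm, xyz in self.atoms.items()
            if not nm.startswith("H") and not nm.startswith("D")
        ]
        return np.array(coords) if coords else np.empty((0, 3))


@dataclass
class Structure:
    """Polymer chains plus ligands and waters kept aside.

    ``chains`` maps chain id to ordered polymer residues; ``ligands``
    groups non-water HETATM residues by residue name (e.g. COA, SPD).
    """

    name: str
    chains: dict[str, list[Residue]]
    ligands: dict[str, list[Residue]]
    waters: list[Residue]

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of CA-bearing residues of a chain."""
        return "".join(
            r.one_letter for r in self.chains[chain_id] if "CA" in r.atoms
        )

    def ca_atoms(self, chain_id: str) -> tuple[np.ndarray, list[int]]:
        res = [r for r in self.chains[chain_id] if "CA" in r.atoms]
        if not res:
            return np.empty((0, 3)), []
        return np.array([r.atoms["CA"] for r in res]), [r.seqid for r in res]

    def polymer_residues(self) -> list[Residue]:
        return [r for chain in self.chains.values() for r in chain]

    def residue(self, chain_id: str, seqid: int) -> Residue:
        for r in self.chains[chain_id]:
            if r.seqid == seqid:
                return r
        raise KeyError(f"{chain_id}/{seqid}")


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties prefer altloc 'A', then blank
    def key(a: gemmi.Atom):
        return (-a.occ, 0 if a.altloc == "A" else (1 if a.altloc == "\0" or not a.altloc else 2), a.altloc)

    return sorted(atoms, key=key)[0]


def read_pdb(path: str | Path, name: str | None = None) -> Structure:
    """Parse a PDB file; altlocs resolved to the highest-occupancy copy.

    Ligands (non-water HETATM residues) are retained separately keyed by
    residue name; waters are tagged apart.  A file without any ATOM or
    HETATM record is rejected.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse PDB: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    ligands: dict[str, list[Residue]] = {}
    waters: list[Residue] = []
    for chain in model:
        for res in chain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = {}
            for aname, copies in by_name.items():
                a = _pick_altloc(copies)
                if not np.isfinite([a.pos.x, a.pos.y, a.pos.z]).all():
                    raise ValueError(f"{path}: non-finite coordinate in {res.name} {res.seqid.num}")
                atoms[aname] = np.array([a.pos.x, a.pos.y, a.pos.z])
            r = Residue(chain.name, res.seqid.num, res.seqid.icode.strip(), res.name, atoms)
            if res.name in _WATER_NAMES:
                waters.append(r)
            elif res.het_flag == "H" and res.name not in _THREE_TO_ONE:
                ligands.setdefault(res.name, []).append(r)
            else:
                chains.setdefault(chain.name, []).append(r)
    return Structure(name or path.stem, chains, ligands, waters)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM/HETATM records) via gemmi."""
    st = gemmi.Structure()
    st.name = structure.name
    model = gemmi.Model("1")
    all_chains: dict[str, gemmi.Chain] = {}

    def chain_for(cid: str) -> gemmi.Chain:
        if cid not in all_chains:
            all_chains[cid] = gemmi.Chain(cid)
        return all_chains[cid]

    def add_residue(r: Residue, het: bool):
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.seqid, r.icode or " ")
        res.het_flag = "H" if het else "A"
        for aname, xyz in r.atoms.items():
            atom = gemmi.Atom()
            atom.name = aname
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.element = gemmi.Element(aname[0])
            res.add_atom(atom)
        chain_for(r.chain_id).add_residue(res)

    for residues in structure.chains.values():
        for r in residues:
            add_residue(r, het=False)
    for residues in structure.ligands.values():
        for r in residues:
            add_residue(r, het=True)
    for r in structure.waters:
        add_residue(r, het=True)
    for ch in all_chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation, applied to the mobile set
    translation: np.ndarray  # 3-vector (Å)
    rmsd: float
    n_pairs: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of Q (mobile) onto P.

    Closed-form SVD solution with the reflection branch excluded; the
    returned rotation/translation satisfy Q @ R.T + t ≈ P.  Degenerate
    (collinear or size-mismatched) input is rejected.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) coordinate sets")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    spread = max(np.linalg.norm(Pc), np.linalg.norm(Qc))
    if spread > 0 and S[1] < 1e-9 * max(S[0], 1e-30):
        # both point sets essentially collinear: rotation underdetermined
        raise ValueError("degenerate (collinear) coordinate sets")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = Qc @ R.T - Pc
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(R, t, rmsd, n)


@dataclass
class ChainPairing:
    chain_a: str
    chain_b: str
    identity: float
    n_pairs: int


def ca_rmsd_by_alignment(
    A: Structure,
    B: Structure,
    params: AlignmentParams = AlignmentParams(),
    min_ca: int = 30,
) -> tuple[SuperpositionResult, list[ChainPairing]]:
    """CA RMSD after sequence-alignment pairing.

    Chains are paired greedily by best global sequence identity; CA atoms
    are paired at non-gap aligned columns; a single Kabsch superposition
    is computed over all pairs.  The report lists per-chain-pair
    identities and pair counts (coverage = n_pairs / CA count).
    """
    chains_a = [c for c in A.chains if len(A.chain_sequence(c)) >= min_ca]
    chains_b = [c for c in B.chains if len(B.chain_sequence(c)) >= min_ca]
    if not chains_a or not chains_b:
        raise ValueError(f"each structure needs a chain with >= {min_ca} CA atoms")
    candidates = []
    for ca in chains_a:
        ra = ProteinRecord(f"A/{ca}", A.chain_sequence(ca), source="user")
        for cb in chains_b:
            rb = ProteinRecord(f"B/{cb}", B.chain_sequence(cb), source="user")
            ident = global_align(ra, rb, params).identity
            candidates.append((ident, ca, cb))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairings: list[tuple[str, str, float]] = []
    for ident, ca, cb in candidates:
        if ca in used_a or cb in used_b:
            continue
        used_a.add(ca)
        used_b.add(cb)
        pairings.append((ca, cb, ident))

    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend, "global")
    P_all, Q_all, report = [], [], []
    for ca, cb, ident in pairings:
        seq_a, seq_b = A.chain_sequence(ca), B.chain_sequence(cb)
        coords_a, _ = A.ca_atoms(ca)
        coords_b, _ = B.ca_atoms(cb)
        idx = aligner.align(seq_a, seq_b)[0].indices
        pair_count = 0
        for ia, ib in idx.T:
            if ia >= 0 and ib >= 0:
                P_all.append(coords_a[ia])
                Q_all.append(coords_b[ib])
                pair_count += 1
        report.append(ChainPairing(ca, cb, ident, pair_count))
    if not P_all:
        raise ValueError("no alignable CA pairs between structures")
    sup = kabsch_superpose(np.array(P_all), np.array(Q_all))
    return sup, report


@dataclass(frozen=True)
class PocketPosition:
    seqid: int
    aa: str  # one-letter residue code
    role: str = "contact"  # h-bond | vdw | catalytic | water-mediated | contact


@dataclass
class PocketProfile:
    """Pocket composition with its electrostatic classification."""

    positions: list[PocketPosition]
    net_charge: float
    counts: dict[str, int]
    electro_class: str  # acidic | basic | neutral
    n_waters: int = 0
    source: str = ""


@dataclass(frozen=True)
class ChargeModel:
    """Formal per-residue charge at neutral pH (His fractional)."""

    charges: Mapping[str, float] = field(
        default_factory=lambda: {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}
    )
    acidic_threshold: float = -1.0
    basic_threshold: float = 1.0

    def charge_of(self, aa: str) -> float:
        aa = aa.upper()
        if len(aa) == 3:
            aa = three_to_one(aa)
        if aa not in _ONE_TO_THREE and aa != "X":
            warnings.warn(f"unknown residue {aa!r} treated as charge 0")
            return 0.0
        return self.charges.get(aa, 0.0)

    def classify(self, net: float) -> str:
        if net <= self.acidic_threshold:
            return "acidic"
        if net >= self.basic_threshold:
            return "basic"
        return "neutral"


_ACIDIC = set("DE")
_BASIC = set("KRH")
_POLAR = set("STNQYC")


def _category_counts(aas: Sequence[str]) -> dict[str, int]:
    counts = {"acidic": 0, "basic": 0, "polar": 0, "hydrophobic": 0}
    for aa in aas:
        if aa in _ACIDIC:
            counts["acidic"] += 1
        elif aa in _BASIC:
            counts["basic"] += 1
        elif aa in _POLAR:
            counts["polar"] += 1
        else:
            counts["hydrophobic"] += 1
    return counts


def pocket_charge(
    positions: Sequence[PocketPosition], model: ChargeModel = ChargeModel()
) -> tuple[float, str]:
    """Net formal charge of the pocket and its electrostatic class."""
    if not positions:
        raise ValueError("pocket position list is empty")
    net = sum(model.charge_of(p.aa) for p in positions)
    return net, model.classify(net)


def _profile_from_positions(
    positions: list[PocketPosition],
    model: ChargeModel,
    n_waters: int = 0,
    source: str = "",
) -> PocketProfile:
    if positions:
        net, cls = pocket_charge(positions, model)
    else:
        net, cls = 0.0, "neutral"
    return PocketProfile(
        positions,
        net,
        _category_counts([p.aa for p in positions]),
        cls,
        n_waters,
        source,
    )


def parse_position(token: str) -> tuple[int, str]:
    """Parse a 'D314'-style residue token into (seqid, one-letter code)."""
    aa, num = token[0].upper(), token[1:]
    if aa not in _ONE_TO_THREE or not num.isdigit():
        raise ValueError(f"cannot parse pocket position {token!r}")
    return int(num), aa


def extract_pocket(
    structure: Structure | None,
    anchor: str = "",
    radius: float = 4.5,
    residues: Sequence | None = None,
    model: ChargeModel = ChargeModel(),
) -> PocketProfile:
    """Pocket residues around a bound ligand, or an explicit list.

    Ligand mode (``anchor`` = HETATM residue name, e.g. "SPD"): every
    polymer residue with a heavy atom within ``radius`` Å of any ligand
    heavy atom becomes a pocket position; waters inside the radius are
    counted but never contribute positions or charge.  List mode
    (``residues`` = 'D314'-style tokens or (seqid, aa[, role]) tuples):
    positions are taken verbatim.
    """
    if residues is not None:
        positions = []
        for item in residues:
            if isinstance(item, str):
                seqid, aa = parse_position(item)
                positions.append(PocketPosition(seqid, aa))
            else:
                seqid, aa = item[0], item[1]
                role = item[2] if len(item) > 2 else "contact"
                if len(aa) == 3:
                    aa = three_to_one(aa)
                positions.append(PocketPosition(int(seqid), aa.upper(), role))
        return _profile_from_positions(positions, model, source="explicit list")

    if not anchor or structure is None:
        raise ValueError("provide a ligand anchor name or an explicit residue list")
    if anchor not in structure.ligands:
        available = sorted(structure.ligands)
        raise ValueError(
            f"ligand {anchor!r} not found; available HETATM codes: {available}"
        )
    lig_coords = np.vstack(
        [r.heavy_coords() for r in structure.ligands[anchor]]
    )
    positions = []
    if radius > 0:
        for res in structure.polymer_residues():
            coords = res.heavy_coords()
            if len(coords) and cdist(coords, lig_coords).min() <= radius:
                positions.append(PocketPosition(res.seqid, res.one_letter))
    n_waters = 0
    if radius > 0:
        for w in structure.waters:
            coords = w.heavy_coords()
            if len(coords) and cdist(coords, lig_coords).min() <= radius:
                n_waters += 1
    return _profile_from_positions(
        positions, model, n_waters=n_waters, source=f"ligand {anchor} @ {radius} Å"
    )


class MappingError(ValueError):
    """Template-to-query pocket mapping refused (homology too low)."""


def map_pocket_to_query(
    template: ProteinRecord,
    profile: PocketProfile,
    query: ProteinRecord,
    params: AlignmentParams = AlignmentParams(),
    identity_floor: float = 0.20,
    numbering: Mapping[int, int] | None = None,
    model: ChargeModel = ChargeModel(),
) -> tuple[PocketProfile, list[PocketPosition]]:
    """Map a template pocket onto a homologous query through alignment.

    ``numbering`` maps template residue seqids to 0-based positions in
    the template sequence (default: seqid - 1, i.e. 1-based sequential
    numbering).  Template positions falling in query gaps are returned
    as the unresolved list; the charge is recomputed on the mapped query
    residues.  Mapping is refused below the identity floor, where a
    pocket transferred by alignment is unreliable.
    """
    res = global_align(template, query, params)
    if res.identity < identity_floor:
        raise MappingError(
            f"global identity {res.identity:.1%} between {template.id} and "
            f"{query.id} is below the {identity_floor:.0%} floor; pocket "
            f"mapping would be unreliable"
        )
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend, "global")
    idx = aligner.align(template.sequence, query.sequence)[0].indices
    t_to_q = {int(ti): int(qi) for ti, qi in idx.T if ti >= 0}
    mapped: list[PocketPosition] = []
    unresolved: list[PocketPosition] = []
    for pos in profile.positions:
        t_index = numbering[pos.seqid] if numbering is not None else pos.seqid - 1
        if t_index < 0 or t_index >= len(template.sequence):
            raise ValueError(
                f"template position {pos.aa}{pos.seqid} outside sequence of {template.id}"
            )
        q_index = t_to_q.get(t_index, -1)
        if q_index < 0:
            unresolved.append(pos)
        else:
            mapped.append(
                PocketPosition(q_index + 1, query.sequence[q_index], pos.role)
            )
    prof = _profile_from_positions(
        mapped, model, source=f"mapped from {template.id} onto {query.id}"
    )
    return prof, unresolved


def load_reference_pockets(model: ChargeModel = ChargeModel()) -> dict:
    """Bundled reference pocket tables as ready-made profiles.

    Returns a dict with, per reference enzyme, the pocket
    :class:`PocketProfile`, the catalytic histidine position and the
    acceptor-class label, plus the shared CoA-site residue list.
    """
    import json
    from importlib.resources import files

    raw = json.loads(
        files("bahdscope.data").joinpath("reference_pockets.json").read_text()
    )
    out: dict = {"labels": raw["labels"], "coa_site": raw["coa_site"]}
    for key in ("AtSHT", "AtSDT"):
        entry = raw[key]
        positions = []
        for item in entry["acceptor_pocket"]:
            seqid, aa = parse_position(item["position"])
            positions.append(PocketPosition(seqid, aa, item["role"]))
        profile = _profile_from_positions(
            positions, model, source=f"published {key} acceptor pocket"
        )
        his_pos, his_aa = parse_position(entry["catalytic_his"])
        out[key] = {
            "gene": entry["gene"],
            "pdb": entry["pdb"],
            "acceptor_class": entry["acceptor_class"],
            "catalytic_his": his_pos,
            "pocket": profile,
        }
    return out
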