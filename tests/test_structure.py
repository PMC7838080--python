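import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bahdscope as bs
from bahdscope.seqio_motifs import ProteinRecord
from bahdscope.structure_pocket import (
    ChargeModel,
    MappingError,
    PocketPosition,
    Residue,
    Structure,
    parse_position,
    pocket_charge,
)

from .oracles import kabsch_rmsd_by_optimizer

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.182  -5.033  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  HIS A   3       4.000   1.000   0.000  1.00  0.00           C
END
"""


class TestReadWritePDB:
    def test_minimal_three_atoms(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        s = bs.read_pdb(p)
        res = s.chains["A"][0]
        assert set(res.atoms) == {"N", "CA", "C"}
        assert res.atoms["CA"] == pytest.approx([11.639, 6.071, -5.147])

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        s = bs.read_pdb(p)
        assert s.chains["A"][0].atoms["CA"][0] == pytest.approx(1.0)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError, match="no ATOM"):
            bs.read_pdb(p)

    def test_synthetic_helix_roundtrip_to_format_precision(self, tmp_path):
        s = bs.make_toy_structure(40, rng=1)
        path = tmp_path / "helix.pdb"
        bs.write_pdb(s, path)
        back = bs.read_pdb(path)
        orig, _ = s.ca_atoms("A")
        reread, _ = back.ca_atoms("A")
        assert np.allclose(orig, reread, atol=1e-3)

    def test_ligand_and_waters_kept_aside(self, tmp_path):
        text = MINIMAL_PDB.replace("END\n", "")
        text += "HETATM    4  N1  SPD A 501       5.000   5.000   5.000  1.00  0.00           N\n"
        text += "HETATM    5  O   HOH A 601       8.000   8.000   8.000  1.00  0.00           O\n"
        text += "END\n"
        p = tmp_path / "lig.pdb"
        p.write_text(text)
        s = bs.read_pdb(p)
        assert "SPD" in s.ligands
        assert len(s.waters) == 1
        assert "SPD" not in s.chains.get("A", [])


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        P = rng.normal(size=(10, 3))
        sup = bs.kabsch_superpose(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self, rng):
        from scipy.spatial.transform import Rotation

        P = rng.normal(size=(25, 3))
        R = Rotation.random(random_state=7).as_matrix()
        Q = P @ R.T + np.array([5.0, -3.0, 12.0])
        sup = bs.kabsch_superpose(P, Q)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(sup.transform(Q), P, atol=1e-6)

    def test_matches_numerical_optimizer_on_noisy_pairs(self, rng):
        P = rng.normal(size=(10, 3)) * 5
        Q = P + rng.normal(0.0, 0.5, size=P.shape)
        sup = bs.kabsch_superpose(P, Q)
        assert sup.rmsd == pytest.approx(kabsch_rmsd_by_optimizer(P, Q), abs=1e-4)

    def test_reflection_never_chosen(self, rng):
        P = rng.normal(size=(12, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored copy
        sup = bs.kabsch_superpose(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)
        assert sup.rmsd > 0.1

    def test_degenerate_collinear_rejected(self):
        P = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            bs.kabsch_superpose(P, P + 1.0)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            bs.kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_superposed_rmsd_never_exceeds_raw(self, rng):
        for _ in range(10):
            P = rng.normal(size=(8, 3)) * 3
            Q = rng.normal(size=(8, 3)) * 3
            raw = np.sqrt(((P - Q) ** 2).sum() / 8)
            assert bs.kabsch_superpose(P, Q).rmsd <= raw + 1e-9


class TestCaRmsdByAlignment:
    def test_self_gives_zero_and_full_pairing(self):
        s = bs.make_toy_structure(60, rng=2)
        sup, report = bs.ca_rmsd_by_alignment(s, s)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert sup.n_pairs == 60
        assert report[0].identity == 1.0

    def test_rigidly_moved_copy_gives_zero(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        s1 = bs.make_toy_structure(60, sequence=seq)
        s2 = bs.make_toy_structure(60, rigid_transform=True, rng=5, sequence=seq)
        sup, _ = bs.ca_rmsd_by_alignment(s1, s2)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rigid_invariance_of_rmsd(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50))
        s1 = bs.make_toy_structure(50, sequence=seq)
        s2 = bs.make_toy_structure(50, sigma=0.4, rng=3, sequence=seq)
        base, _ = bs.ca_rmsd_by_alignment(s1, s2)
        s2_moved = bs.make_toy_structure(50, sigma=0.4, rng=3, sequence=seq)
        coords = np.array([r.atoms["CA"] for r in s2_moved.chains["A"]])
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=11).as_matrix()
        moved = coords @ R.T + np.array([3.0, 4.0, 5.0])
        for r, xyz in zip(s2_moved.chains["A"], moved):
            r.atoms["CA"] = xyz
        after, _ = bs.ca_rmsd_by_alignment(s1, s2_moved)
        assert after.rmsd == pytest.approx(base.rmsd, abs=1e-6)


class TestExtractPocket:
    def _structure_with_ligand(self):
        residues = [
            Residue("A", 1, "", "ASP", {"CA": np.array([0.0, 0.0, 0.0])}),
            Residue("A", 2, "", "LYS", {"CA": np.array([3.0, 0.0, 0.0])}),
            Residue("A", 3, "", "GLY", {"CA": np.array([20.0, 0.0, 0.0])}),
        ]
        ligand = Residue("A", 501, "", "SPD", {"N1": np.array([1.5, 0.0, 0.0])})
        water = Residue("A", 601, "", "HOH", {"O": np.array([1.5, 1.0, 0.0])})
        return Structure("toy", {"A": residues}, {"SPD": [ligand]}, [water])

    def test_planted_geometry_two_residues_in_radius(self):
        s = self._structure_with_ligand()
        prof = bs.extract_pocket(s, anchor="SPD", radius=4.5)
        assert {(p.seqid, p.aa) for p in prof.positions} == {(1, "D"), (2, "K")}
        assert prof.n_waters == 1

    def test_radius_zero_empty(self):
        prof = bs.extract_pocket(self._structure_with_ligand(), anchor="SPD", radius=0.0)
        assert prof.positions == []

    def test_monotone_in_radius(self):
        s = self._structure_with_ligand()
        small = bs.extract_pocket(s, anchor="SPD", radius=2.0)
        big = bs.extract_pocket(s, anchor="SPD", radius=25.0)
        assert {p.seqid for p in small.positions} <= {p.seqid for p in big.positions}

    def test_missing_ligand_names_available_codes(self):
        with pytest.raises(ValueError, match="SPD"):
            bs.extract_pocket(self._structure_with_ligand(), anchor="COA")

    def test_explicit_list_taken_verbatim(self):
        tokens = ["T33", "I37", "G290", "C292", "T312", "D314", "V386", "H411", "D416"]
        prof = bs.extract_pocket(None, residues=tokens)
        assert len(prof.positions) == 9


class TestPocketCharge:
    def test_reference_pocket_charges_under_default_model(self):
        refs = bs.load_reference_pockets()
        sht = refs["AtSHT"]["pocket"]
        sdt = refs["AtSDT"]["pocket"]
        # two Asp plus a fractional His; three acidic residues respectively
        assert sht.net_charge == pytest.approx(-1.9)
        assert sht.electro_class == "acidic"
        assert sdt.net_charge == pytest.approx(-3.0)
        assert sdt.electro_class == "acidic"

    def test_basic_pocket_classified_basic(self):
        positions = [PocketPosition(i, aa) for i, aa in enumerate("RRKST", start=1)]
        net, cls = pocket_charge(positions)
        assert net == pytest.approx(3.0)
        assert cls == "basic"

    def test_unknown_residue_warns_and_counts_zero(self):
        with pytest.warns(UserWarning, match="unknown residue"):
            net, _ = pocket_charge([PocketPosition(1, "U"), PocketPosition(2, "D")])
        assert net == pytest.approx(-1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("DEKRHASTNQ"), min_size=1, max_size=12))
    def test_permutation_invariant_and_additive(self, aas):
        positions = [PocketPosition(i + 1, aa) for i, aa in enumerate(aas)]
        net, _ = pocket_charge(positions)
        net_rev, _ = pocket_charge(positions[::-1])
        assert net == pytest.approx(net_rev)
        if len(positions) > 1:
            n1, _ = pocket_charge(positions[:1])
            n2, _ = pocket_charge(positions[1:])
            assert net == pytest.approx(n1 + n2)


class TestMapPocket:
    def test_self_mapping_identical(self, rng):
        refs = bs.load_reference_pockets()
        pocket = [(p.seqid, p.aa) for p in refs["AtSDT"]["pocket"].positions]
        scaffold = bs.make_scaffold_with_pocket(pocket, 451, rng, "sdt_scaffold")
        prof, unresolved = bs.map_pocket_to_query(
            scaffold, refs["AtSDT"]["pocket"], scaffold
        )
        assert unresolved == []
        assert {(p.seqid, p.aa) for p in prof.positions} == set(pocket)
        assert prof.net_charge == pytest.approx(-3.0)

    def test_single_pocket_substitution_shifts_charge_by_one(self, rng):
        refs = bs.load_reference_pockets()
        pocket = [(p.seqid, p.aa) for p in refs["AtSDT"]["pocket"].positions]
        scaffold = bs.make_scaffold_with_pocket(pocket, 451, rng, "s")
        seq = list(scaffold.sequence)
        assert seq[315] == "D"  # D316
        seq[315] = "A"
        mutant = ProteinRecord("mut", "".join(seq))
        prof, _ = bs.map_pocket_to_query(scaffold, refs["AtSDT"]["pocket"], mutant)
        assert prof.net_charge == pytest.approx(-2.0)

    def test_identity_below_floor_refused(self, rng):
        refs = bs.load_reference_pockets()
        pocket = [(p.seqid, p.aa) for p in refs["AtSDT"]["pocket"].positions]
        scaffold = bs.make_scaffold_with_pocket(pocket, 451, rng, "s")
        unrelated = bs.make_seed_sequence(451, np.random.default_rng(999), "far")
        far = ProteinRecord(
            "far", bs.evolve_family(unrelated, 1, 0.9, rng=rng, protect_motifs=False)[0].sequence
        )
        with pytest.raises(MappingError, match="floor"):
            bs.map_pocket_to_query(scaffold, refs["AtSDT"]["pocket"], far)


def test_parse_position():
    assert parse_position("D314") == (314, "D")
    with pytest.raises(ValueError):
        parse_position("314D")


def test_reference_tables_complete():
    refs = bs.load_reference_pockets()
    assert len(refs["AtSHT"]["pocket"].positions) == 9
    assert len(refs["AtSDT"]["pocket"].positions) == 13
    assert refs["AtSHT"]["catalytic_his"] == 155
    assert refs["AtSDT"]["catalytic_his"] == 169
    assert set(refs["coa_site"]) == {"R246", "R263", "S387", "T390", "E265", "T262", "R298"}
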