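import math

import numpy as np
import pytest

from ssv.fixtures import make_toy_chain
from ssv.pocket import (
    EmptyPocketError,
    MappingQualityError,
    PocketDefinition,
    extract_pocket,
    kabsch_superpose,
    map_pocket,
    read_pocket_tsv,
    residues_near_ligand,
    whole_structure_pocket,
    write_pocket_tsv,
)
from ssv.structure_io import Atom, Residue, Structure


def _atom(name, x, y, z, serial=1, hetero=False):
    return Atom(
        serial=serial, name=name, element=name[0], alt_loc="",
        coords=(x, y, z), occupancy=1.0, is_hetero=hetero,
    )


def _ligand_structure():
    """Ligand atom at origin; residue A at 6.4 Å, residue B at 6.6 Å."""
    s = Structure(id="ligtoy")
    s.residues = [
        Residue("A", 1, "", "ALA", [_atom("CB", 6.4, 0, 0)]),
        Residue("A", 2, "", "GLY", [_atom("CA", 6.6, 0, 0, serial=2)]),
    ]
    s.ligands = [Residue("A", 500, "", "BGC", [_atom("C1", 0, 0, 0, serial=3, hetero=True)])]
    return s


class TestResiduesNearLigand:
    def test_boundary_is_inclusive(self):
        pocket = residues_near_ligand(_ligand_structure(), ("A", 500, ""), cutoff=6.5)
        assert [(c, n) for c, n, _, _ in pocket.residues] == [("A", 1)]

    def test_exact_boundary_distance_included(self):
        pocket = residues_near_ligand(_ligand_structure(), ("A", 500, ""), cutoff=6.6)
        assert len(pocket) == 2

    def test_missing_ligand_raises(self):
        with pytest.raises(KeyError):
            residues_near_ligand(_ligand_structure(), ("A", 999, ""), cutoff=6.5)

    def test_no_residue_in_range_raises(self):
        with pytest.raises(EmptyPocketError):
            residues_near_ligand(_ligand_structure(), ("A", 500, ""), cutoff=1.0)

    def test_zero_cutoff_rejected(self):
        with pytest.raises(ValueError):
            residues_near_ligand(_ligand_structure(), ("A", 500, ""), cutoff=0.0)

    def test_monotone_in_cutoff(self):
        s = _ligand_structure()
        keys_small = set(residues_near_ligand(s, ("A", 500, ""), 6.5).keys())
        keys_large = set(residues_near_ligand(s, ("A", 500, ""), 7.5).keys())
        assert keys_small <= keys_large


class TestKabsch:
    def test_identity_on_equal_sets(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-10)
        assert rmsd == pytest.approx(0, abs=1e-10)

    def test_recovers_rotation_about_z(self):
        pts = np.array([[1, 0, 0], [0, 2, 0], [0, 0, 3], [1, 1, 1]], float)
        theta = math.pi / 2
        Rz = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        target = pts @ Rz.T
        R, t, rmsd = kabsch_superpose(pts, target)
        assert rmsd == pytest.approx(0, abs=1e-9)
        assert np.allclose(R, Rz, atol=1e-9)

    def test_displaced_point_instance_matches_grid_oracle(self):
        # Frozen oracle value: Nelder-Mead over rotation vectors and
        # translations on this exact instance converges to 0.2519158498.
        P = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [4, 4, 0]], float)
        Q = P.copy()
        Q[3, 2] += 1.0
        _, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.2519158498, abs=1e-8)

    def test_transform_achieves_reported_rmsd(self):
        rng = np.random.default_rng(11)
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(P, Q)
        moved = P @ R.T + t
        achieved = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
        assert achieved == pytest.approx(rmsd, abs=1e-6)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_rmsd_invariant_under_rigid_premotion(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(8, 3))
        Q = rng.normal(size=(8, 3))
        _, _, rmsd0 = kabsch_superpose(P, Q)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = 1.234
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R_pre = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
        P2 = P @ R_pre.T + np.array([3.0, -2.0, 7.0])
        _, _, rmsd1 = kabsch_superpose(P2, Q)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose([[0, 0, 0], [1, 1, 1]], [[0, 0, 0], [1, 1, 1]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestMapPocket:
    def test_identity_mapping(self):
        ref = make_toy_chain("ACDEFGH", seed=1, structure_id="ref")
        pocket = PocketDefinition(
            reference_id="ref",
            residues=[("A", 2, "", "CYS"), ("A", 5, "", "PHE")],
            cutoff=6.5,
        )
        mapped, unmapped = map_pocket(ref, pocket, ref)
        assert unmapped == []
        assert mapped.residues == pocket.residues

    def test_substitution_keeps_position_updates_name(self):
        ref = make_toy_chain("ACDEFGH", seed=1, structure_id="ref")
        target = make_toy_chain("ACDWFGH", seed=1, structure_id="tgt")  # E4->W
        pocket = PocketDefinition(
            reference_id="ref", residues=[("A", 4, "", "GLU")], cutoff=6.5
        )
        mapped, unmapped = map_pocket(ref, pocket, target)
        assert unmapped == []
        assert mapped.residues == [("A", 4, "", "TRP")]

    def test_nterminal_insertion_shifts_numbering(self):
        # Brute-force expectation: a 2-residue N-terminal insertion keeps the
        # optimal global alignment as identity on the common suffix, so every
        # mapped seq_num is shifted by exactly 2.
        ref = make_toy_chain("ACDEFGHIKL", seed=1, structure_id="ref")
        target = make_toy_chain("MWACDEFGHIKL", seed=2, structure_id="tgt")
        pocket = PocketDefinition(
            reference_id="ref",
            residues=[("A", 3, "", "ASP"), ("A", 7, "", "HIS")],
            cutoff=6.5,
        )
        mapped, unmapped = map_pocket(ref, pocket, target)
        assert unmapped == []
        assert [(s, n) for _, s, _, n in mapped.residues] == [
            (5, "ASP"), (9, "HIS")
        ]

    def test_gap_position_reported_unmapped(self):
        ref = make_toy_chain("ACDEFGHIKL", seed=1, structure_id="ref")
        target = make_toy_chain("ACDEGHIKL", seed=2, structure_id="tgt")  # F5 deleted
        pocket = PocketDefinition(
            reference_id="ref",
            residues=[("A", 5, "", "PHE"), ("A", 8, "", "ILE")],
            cutoff=6.5,
        )
        mapped, unmapped = map_pocket(ref, pocket, target)
        assert [("A", 5, "", "PHE")] == unmapped
        assert [(s, n) for _, s, _, n in mapped.residues] == [(7, "ILE")]

    def test_identity_floor_enforced(self):
        ref = make_toy_chain("AAAAAAAAAA", seed=1, structure_id="ref")
        target = make_toy_chain("WWWWWWWWWW", seed=2, structure_id="tgt")
        pocket = PocketDefinition(
            reference_id="ref", residues=[("A", 1, "", "ALA")], cutoff=6.5
        )
        with pytest.raises(MappingQualityError):
            map_pocket(ref, pocket, target, identity_floor=0.9)


class TestExtractPocket:
    def test_subset_extraction(self, small_chain):
        pocket = PocketDefinition(
            reference_id=small_chain.id,
            residues=[("A", 2, "", "CYS"), ("A", 4, "", "GLU")],
            cutoff=6.5,
        )
        sub = extract_pocket(small_chain, pocket)
        assert [r.seq_num for r in sub.residues] == [2, 4]
        assert sub.residues[0].atoms == small_chain.residues[1].atoms

    def test_full_pocket_is_identity(self, small_chain):
        pocket = whole_structure_pocket(small_chain)
        sub = extract_pocket(small_chain, pocket)
        assert [r.key for r in sub.residues] == [r.key for r in small_chain.residues]

    def test_missing_residue_named_in_error(self, small_chain):
        pocket = PocketDefinition(
            reference_id=small_chain.id,
            residues=[("A", 99, "", "ALA")],
            cutoff=6.5,
        )
        with pytest.raises(KeyError, match="99"):
            extract_pocket(small_chain, pocket)


class TestPocketTsv:
    def test_round_trip(self, tmp_path, small_chain):
        pocket = whole_structure_pocket(small_chain, cutoff=6.5)
        path = tmp_path / "pocket.tsv"
        write_pocket_tsv(pocket, path)
        back = read_pocket_tsv(path)
        assert back.residues == pocket.residues
        assert back.cutoff == pocket.cutoff
        assert back.reference_id == pocket.reference_id

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError):
            PocketDefinition(
                reference_id="x",
                residues=[("A", 1, "", "ALA"), ("A", 1, "", "ALA")],
                cutoff=6.5,
            )
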