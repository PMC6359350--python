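import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import CLASS_SET_POOL, random_atom_spec
from ssv.fixtures import ToySpec, brute_force_signature, make_toy_structure
from ssv.signature import (
    DEFAULT_GRID,
    N_CLASS_PAIRS,
    CutoffGrid,
    SignatureVector,
    class_pair_index,
    class_pair_labels,
    compute_signature,
    read_signature_tsv,
    signature_distance,
    write_signature_tsv,
)
from ssv.structure_io import PHARMACOPHORE_CLASSES, Structure, assign_pharmacophores


class TestCutoffGrid:
    def test_default_grid_has_101_points(self):
        assert DEFAULT_GRID.n_points == 101
        assert DEFAULT_GRID.dimension == 3636

    def test_points_strictly_increasing(self):
        pts = DEFAULT_GRID.points
        assert np.all(np.diff(pts) > 0)
        assert pts[0] == 0.0
        assert pts[-1] == pytest.approx(10.0)

    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError):
            CutoffGrid(0.0, 10.0, 0.0)
        with pytest.raises(ValueError):
            CutoffGrid(5.0, 5.0, 0.1)


class TestClassPairIndex:
    def test_first_pair_is_zero(self):
        assert class_pair_index("hydrophobic", "hydrophobic") == 0

    def test_last_pair(self):
        assert class_pair_index("neutral", "neutral") == N_CLASS_PAIRS - 1

    def test_symmetry_all_pairs(self):
        for c1 in PHARMACOPHORE_CLASSES:
            for c2 in PHARMACOPHORE_CLASSES:
                assert class_pair_index(c1, c2) == class_pair_index(c2, c1)

    def test_enumeration_yields_36_distinct_values(self):
        values = {
            class_pair_index(c1, c2)
            for c1 in PHARMACOPHORE_CLASSES
            for c2 in PHARMACOPHORE_CLASSES
        }
        assert values == set(range(36))

    def test_matches_label_enumeration(self):
        for idx, (c1, c2) in enumerate(class_pair_labels()):
            assert class_pair_index(c1, c2) == idx

    def test_unknown_class_rejected(self):
        with pytest.raises(KeyError):
            class_pair_index("hydrophobic", "polar")


def _signature_of(structure):
    return compute_signature(structure, assign_pharmacophores(structure))


class TestComputeSignature:
    def test_empty_structure_gives_zero_vector(self):
        sig = compute_signature(Structure(id="empty"), {})
        assert len(sig) == 3636
        assert not sig.values.any()

    def test_worked_two_atom_example(self, two_atom_structure):
        # Single hydrophobic pair at 3.05 Å: HH row flips 0 -> 1 at 3.1 Å.
        sig = _signature_of(two_atom_structure)
        hh = sig.matrix[0]
        assert list(hh[:31]) == [0] * 31  # cutoffs 0.0 .. 3.0
        assert list(hh[31:]) == [1] * 70  # cutoffs 3.1 .. 10.0
        assert sig.values.sum() == hh.sum()

    def test_default_dimension_is_3636(self, toy_chain):
        assert len(_signature_of(toy_chain)) == 3636

    def test_cumulative_monotonicity(self, toy_chain):
        m = _signature_of(toy_chain).matrix
        assert np.all(np.diff(m, axis=1) >= 0)

    def test_rigid_motion_invariance(self, toy_chain):
        sig0 = _signature_of(toy_chain)
        theta = 0.813
        R = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        t = np.array([12.0, -7.0, 3.5])
        moved = Structure(id="moved")
        import copy

        moved.residues = copy.deepcopy(toy_chain.residues)
        from ssv.structure_io import Atom

        for res in moved.residues:
            for i, atom in enumerate(res.atoms):
                new = R @ np.asarray(atom.coords) + t
                res.atoms[i] = Atom(
                    serial=atom.serial, name=atom.name, element=atom.element,
                    alt_loc=atom.alt_loc, coords=tuple(float(v) for v in new),
                    occupancy=atom.occupancy, is_hetero=atom.is_hetero,
                )
        assert np.array_equal(_signature_of(moved).values, sig0.values)

    def test_permutation_invariance(self, toy_chain):
        sig0 = _signature_of(toy_chain)
        shuffled = Structure(id=toy_chain.id, residues=list(reversed(toy_chain.residues)))
        assert np.array_equal(_signature_of(shuffled).values, sig0.values)

    def test_pair_count_conservation_single_class(self):
        # With single-class typing, the 36 rows partition the pairs: the
        # row sums at the final cutoff equal the number of in-range pairs.
        atoms = random_atom_spec(20, seed=9, extent=4.0)
        single = [(frozenset([sorted(cs)[0]]), xyz) for cs, xyz in atoms]
        sig = brute_force_signature(single)
        n_pairs_in_range = 0
        for i in range(len(single)):
            for j in range(i + 1, len(single)):
                d = math.dist(single[i][1], single[j][1])
                if d <= 10.0:
                    n_pairs_in_range += 1
        assert sig.matrix[:, -1].sum() == n_pairs_in_range
        n = len(single)
        assert n_pairs_in_range <= n * (n - 1) // 2

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        atoms = random_atom_spec(int(rng.integers(2, 35)), seed=seed + 100)
        structure = make_toy_structure(ToySpec(atoms=atoms))
        sig = _signature_of(structure)
        oracle = brute_force_signature(atoms)
        assert np.array_equal(sig.values, oracle.values)

    def test_multi_class_atom_increments_each_derived_pair_once(self):
        atoms = [
            (frozenset({"negative", "acceptor"}), (0.0, 0.0, 0.0)),
            (frozenset({"positive", "donor"}), (2.0, 0.0, 0.0)),
        ]
        sig = brute_force_signature(atoms)
        m = sig.matrix
        expected_rows = {
            class_pair_index("negative", "positive"),
            class_pair_index("negative", "donor"),
            class_pair_index("acceptor", "positive"),
            class_pair_index("acceptor", "donor"),
        }
        for row in range(36):
            assert m[row, -1] == (1 if row in expected_rows else 0)
        structure = make_toy_structure(ToySpec(atoms=atoms))
        assert np.array_equal(_signature_of(structure).values, sig.values)

    def test_pairs_beyond_dmax_contribute_nothing(self):
        atoms = [
            (frozenset({"hydrophobic"}), (0.0, 0.0, 0.0)),
            (frozenset({"hydrophobic"}), (10.5, 0.0, 0.0)),
        ]
        structure = make_toy_structure(ToySpec(atoms=atoms))
        assert not _signature_of(structure).values.any()

    def test_single_atom_zero_vector(self):
        atoms = [(frozenset({"hydrophobic"}), (0.0, 0.0, 0.0))]
        structure = make_toy_structure(ToySpec(atoms=atoms))
        assert not _signature_of(structure).values.any()


class TestSignatureDistance:
    def test_identical_vectors_zero(self, toy_chain):
        sig = _signature_of(toy_chain)
        assert signature_distance(sig, sig) == 0.0

    def test_pythagorean_example(self):
        a = SignatureVector(values=np.zeros(3636, dtype=np.int64))
        values = np.zeros(3636, dtype=np.int64)
        values[0], values[100] = 3, 4
        b = SignatureVector(values=values)
        assert signature_distance(a, b) == pytest.approx(5.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry_on_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        a = SignatureVector(values=rng.integers(0, 50, size=3636))
        b = SignatureVector(values=rng.integers(0, 50, size=3636))
        assert signature_distance(a, b) == signature_distance(b, a)

    def test_dimension_mismatch_rejected(self):
        a = SignatureVector(values=np.zeros(3636, dtype=np.int64))
        small_grid = CutoffGrid(0.0, 5.0, 0.1)
        b = SignatureVector(
            values=np.zeros(small_grid.dimension, dtype=np.int64), grid=small_grid
        )
        with pytest.raises(ValueError):
            signature_distance(a, b)


class TestSignatureTsv:
    def test_round_trip(self, tmp_path, toy_chain, small_chain):
        sigs = [_signature_of(toy_chain), _signature_of(small_chain)]
        path = tmp_path / "sigs.tsv"
        write_signature_tsv(sigs, path)
        back = read_signature_tsv(path)
        assert [s.structure_id for s in back] == [s.structure_id for s in sigs]
        for orig, rt in zip(sigs, back):
            assert np.array_equal(orig.values, rt.values)

    def test_header_mismatch_detected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\twrong\n")
        with pytest.raises(ValueError):
            read_signature_tsv(path)
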