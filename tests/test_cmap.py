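"""Contact-map derivation, perturbations, dummy loops and file formats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmap2struct import cmap as cm
from cmap2struct.structio import Atom, Chain, Residue, Structure

from conftest import random_ternary_map


def _point_structure(points, chain_lengths=None):
    """Single- or multi-chain CA-only structure from raw points."""
    points = np.asarray(points, float)
    chain_lengths = chain_lengths or [len(points)]
    s = Structure()
    pos = 0
    for ci, n in enumerate(chain_lengths):
        ch = Chain(chr(ord("A") + ci))
        for k in range(n):
            r = Residue(ch.chain_id, k + 1, "ALA")
            r.atoms.append(Atom("CA", "C", points[pos]))
            ch.residues.append(r)
            pos += 1
        s.chains.append(ch)
    return s


class TestDerive:
    def test_collinear_points_8A(self):
        s = _point_structure([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        m = cm.derive_cmap(s, threshold=8.0)
        assert (m.matrix == 1).all()

    def test_collinear_points_5A(self):
        s = _point_structure([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        m = cm.derive_cmap(s, threshold=5.0)
        assert m.matrix[0, 1] == m.matrix[1, 2] == 1
        assert m.matrix[0, 2] == 0

    def test_matches_brute_force_on_helix(self, helix30, helix30_map):
        coords = [r.atom("CA").coord for r in helix30.residues()]
        for i in range(30):
            for j in range(30):
                expect = 1 if np.linalg.norm(coords[i] - coords[j]) <= 8.0 else 0
                assert helix30_map.matrix[i, j] == expect

    def test_cb_mode_falls_back_for_glycine(self, helix30):
        m = cm.derive_cmap(helix30, threshold=8.0, atom_mode="CB")
        assert m.meta["atom_mode"] == "CB"

    def test_bad_threshold(self, helix30):
        with pytest.raises(ValueError):
            cm.derive_cmap(helix30, threshold=-1.0)


class TestContactDensity:
    def test_all_contacts(self):
        m = cm.ContactMap(np.ones((3, 3), dtype=int))
        assert cm.contact_density(m) == 2.0

    def test_no_contacts(self):
        m = cm.ContactMap(np.eye(3, dtype=int))
        assert cm.contact_density(m) == 0.0

    def test_matches_brute_force(self):
        m = random_ternary_map(50, seed=7)
        c = [(m.matrix[i] == 1).sum() - 1 for i in range(50)]
        assert cm.contact_density(m) == pytest.approx(np.mean(c))


class TestPerturbations:
    def test_positive_only_definition(self):
        m = random_ternary_map(20, seed=1, unknown_frac=0.0)
        p = cm.positive_only(m)
        assert (p.matrix[m.matrix == 1] == 1).all()
        off = ~np.eye(20, dtype=bool)
        assert set(np.unique(p.matrix[off])) <= {1, -1}

    def test_positive_only_idempotent_and_preserves_ones(self):
        m = random_ternary_map(30, seed=2)
        p1 = cm.positive_only(m)
        p2 = cm.positive_only(p1)
        assert np.array_equal(p1.matrix, p2.matrix)
        assert p1.counts()[1] == m.counts()[1]

    @pytest.mark.parametrize("fraction", [1.0, 0.9, 0.7, 0.5, 0.3, 0.0])
    def test_reduce_exact_counts(self, fraction):
        m = random_ternary_map(40, seed=3, unknown_frac=0.0)
        K = m.counts()[1] + m.counts()[0]
        r = cm.reduce_cmap(m, fraction, seed=11)
        known_after = r.counts()[1] + r.counts()[0]
        assert known_after == K - int(np.floor((1 - fraction) * K + 0.5))

    def test_reduce_full_fraction_is_identity(self):
        m = random_ternary_map(25, seed=4)
        r = cm.reduce_cmap(m, 1.0, seed=0)
        assert np.array_equal(r.matrix, m.matrix)

    def test_reduce_reproducible(self):
        m = random_ternary_map(30, seed=5)
        a = cm.reduce_cmap(m, 0.5, seed=99)
        b = cm.reduce_cmap(m, 0.5, seed=99)
        assert np.array_equal(a.matrix, b.matrix)

    def test_flip_ones_counts(self):
        m = random_ternary_map(30, seed=6, unknown_frac=0.0)
        n1 = m.counts()[1]
        e = cm.inject_errors(m, 0.5, mode="flip_ones", seed=0)
        # counting uses round-half-away-from-zero
        assert e.counts()[1] == n1 - int(np.floor(0.5 * n1 + 0.5))
        # flipped entries became 0, none became unknown
        assert e.counts()[-1] == m.counts()[-1]

    def test_flip_both_counts(self):
        m = random_ternary_map(30, seed=8, unknown_frac=0.0)
        K = m.counts()[1] + m.counts()[0]
        e = cm.inject_errors(m, 0.7, mode="flip_both", seed=1)
        n_diff = int((e.matrix != m.matrix)[np.triu_indices(30, 1)].sum())
        assert n_diff == int(np.floor((1.0 - 0.7) * K + 0.5))

    def test_identity_at_fraction_one(self):
        m = random_ternary_map(20, seed=9)
        for mode in ("flip_ones", "flip_both"):
            e = cm.inject_errors(m, 1.0, mode=mode, seed=5)
            assert np.array_equal(e.matrix, m.matrix)

    def test_invalid_mode(self):
        m = random_ternary_map(10, seed=0)
        with pytest.raises(ValueError):
            cm.inject_errors(m, 0.5, mode="bogus", seed=0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), fraction=st.floats(0.0, 1.0))
    def test_outputs_stay_symmetric_ternary(self, seed, fraction):
        m = random_ternary_map(15, seed=seed % 50)
        for out in (
            cm.positive_only(m),
            cm.reduce_cmap(m, fraction, seed),
            cm.inject_errors(m, fraction, "flip_ones", seed),
            cm.inject_errors(m, fraction, "flip_both", seed),
        ):
            assert np.array_equal(out.matrix, out.matrix.T)
            assert np.isin(out.matrix, (-1, 0, 1)).all()


class TestDummyLoops:
    def test_two_chain_example(self):
        s = _point_structure(np.arange(12).reshape(4, 3), chain_lengths=[2, 2])
        m = cm.derive_cmap(s, threshold=100.0)
        aug, mapping = cm.insert_dummy_loops(m, loop_length=3)
        assert aug.L == 7
        assert mapping == {1: 1, 2: 2, 3: 6, 4: 7}
        off = ~np.eye(7, dtype=bool)
        for d in (2, 3, 4):
            assert (aug.matrix[d][off[d]] == -1).all()
        assert aug.dummy_mask.tolist() == [False, False, True, True, True, False, False]

    def test_size_arithmetic(self, tetramer14_map):
        aug, _ = cm.insert_dummy_loops(tetramer14_map, loop_length=15)
        assert aug.L == 56 + 15 * 3

    def test_submatrix_restores_input(self, tetramer14_map):
        aug, mapping = cm.insert_dummy_loops(tetramer14_map, loop_length=6)
        keep = np.array(sorted(v - 1 for v in mapping.values()))
        sub = aug.matrix[np.ix_(keep, keep)]
        assert np.array_equal(sub, tetramer14_map.matrix)

    def test_single_chain_warns_noop(self, helix30_map):
        with pytest.warns(UserWarning):
            out, mapping = cm.insert_dummy_loops(helix30_map, loop_length=5)
        assert out.L == helix30_map.L
        assert mapping == {i + 1: i + 1 for i in range(30)}


class TestFormats:
    def test_matrix_round_trip(self, tmp_path):
        m = random_ternary_map(17, seed=12)
        p = tmp_path / "m.cmap"
        cm.write_cmap(m, p, format="matrix")
        back = cm.read_cmap(p, format="matrix")
        assert np.array_equal(back.matrix, m.matrix)

    def test_rr_list_defaults_unknown(self, tmp_path):
        p = tmp_path / "c.rr"
        p.write_text("# L=3\n1 3 1\n")
        m = cm.read_cmap(p, format="rr_list")
        assert m.matrix[0, 2] == m.matrix[2, 0] == 1
        off = ~np.eye(3, dtype=bool)
        assert (m.matrix[off][m.matrix[off] != 1] == -1).all()

    def test_rr_list_round_trip_known_entries(self, tmp_path):
        m = random_ternary_map(12, seed=13)
        p = tmp_path / "m.rr"
        cm.write_cmap(m, p, format="rr_list")
        back = cm.read_cmap(p, format="rr_list")
        ones = m.matrix == 1
        assert np.array_equal(back.matrix[ones], m.matrix[ones])

    def test_invalid_entry_rejected(self, tmp_path):
        p = tmp_path / "bad.cmap"
        p.write_text("1 2\n2 1\n")
        with pytest.raises(ValueError, match="outside"):
            cm.read_cmap(p)

    def test_asymmetric_rejected(self, tmp_path):
        p = tmp_path / "asym.cmap"
        p.write_text("1 1 0\n0 1 0\n0 0 1\n")
        with pytest.raises(ValueError, match="symmetric|asymmetric"):
            cm.read_cmap(p)
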