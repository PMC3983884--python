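"""Superposition, RMSD family, diameter and rank statistics."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cmap2struct import evalmetrics as ev


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = ev.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(R, np.eye(3), atol=1e-6)

    def test_exact_recovery_of_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        Rz = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        shift = np.array([1.0, -2.0, 3.0])
        target = pts @ Rz.T + shift
        R, t, rmsd = ev.kabsch_superpose(pts, target)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(R, Rz, atol=1e-6)
        assert np.allclose(t, shift, atol=1e-6)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_numeric_optimizer(self):
        """Independent oracle: minimize RMSD over a rotation-vector parametrization."""
        rng = np.random.default_rng(2)
        mobile = rng.normal(size=(5, 3))
        target = rng.normal(size=(5, 3))
        _, _, rmsd = ev.kabsch_superpose(mobile, target)

        cm_m, cm_t = mobile.mean(0), target.mean(0)

        def cost(v):
            R = Rotation.from_rotvec(v).as_matrix()
            moved = (mobile - cm_m) @ R.T + cm_t
            return np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))

        best = min(
            minimize(cost, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for x0 in [np.zeros(3), [1, 1, 1], [-2, 0.5, 1.5], [0, 3, 0]]
        )
        assert rmsd == pytest.approx(best, abs=1e-5)

    def test_two_points_translation_fallback(self):
        R, t, rmsd = ev.kabsch_superpose(np.array([[0.0, 0, 0], [1, 0, 0]]),
                                         np.array([[5.0, 0, 0], [6, 0, 0]]))
        assert np.allclose(R, np.eye(3))
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            ev.kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))


class TestGlobalRmsd:
    def test_self_is_zero(self, tetramer14):
        rmsd, info = ev.global_rmsd(tetramer14, tetramer14)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_mirror_recovered(self, tetramer14):
        mirrored = tetramer14.transformed(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))
        # reflection is not a rigid motion: plain RMSD is large
        plain, _ = ev.global_rmsd(mirrored, tetramer14, mirror_aware=False)
        aware, info = ev.global_rmsd(mirrored, tetramer14, mirror_aware=True)
        assert plain > 1.0
        assert aware == pytest.approx(0.0, abs=1e-6)
        assert info["mirror_used"]

    def test_cyclic_chain_relabel_recovered(self, tetramer14):
        shifted = tetramer14.copy()
        shifted.chains = shifted.chains[1:] + shifted.chains[:1]
        off, _ = ev.global_rmsd(shifted, tetramer14, permute_chains=False)
        on, info = ev.global_rmsd(shifted, tetramer14, permute_chains=True)
        assert on == pytest.approx(0.0, abs=1e-6)
        assert off >= on

    def test_flags_only_lower_rmsd(self, tetramer14):
        rng = np.random.default_rng(3)
        noisy = tetramer14.copy()
        for r in noisy.residues():
            for a in r.atoms:
                a.coord = a.coord + rng.normal(scale=1.0, size=3)
        base, _ = ev.global_rmsd(noisy, tetramer14, mirror_aware=False, permute_chains=False)
        full, _ = ev.global_rmsd(noisy, tetramer14, mirror_aware=True, permute_chains=True)
        assert full <= base + 1e-12

    def test_rigid_motion_invariance(self, tetramer14):
        R = Rotation.from_rotvec([0.2, 0.4, -0.6]).as_matrix()
        moved = tetramer14.transformed(R, np.array([10.0, 0, -5]))
        rmsd, _ = ev.global_rmsd(moved, tetramer14)
        assert rmsd == pytest.approx(0.0, abs=1e-6)


class TestSubsetAndLocal:
    def test_full_selection_equals_global(self, tetramer14):
        rng = np.random.default_rng(4)
        noisy = tetramer14.copy()
        for r in noisy.residues():
            for a in r.atoms:
                a.coord = a.coord + rng.normal(scale=0.3, size=3)
        g, _ = ev.global_rmsd(noisy, tetramer14, mirror_aware=False)
        s = ev.subset_rmsd(noisy, tetramer14, (1, 999), align_on="subset", mirror_aware=False)
        assert s == pytest.approx(g, rel=1e-6)

    def test_self_subset_zero(self, tetramer14):
        assert ev.subset_rmsd(tetramer14, tetramer14, (5, 9)) == pytest.approx(0.0, abs=1e-6)

    def test_displaced_loop_raises_global_not_subset(self, helix30):
        disturbed = helix30.copy()
        for r in list(disturbed.residues())[25:]:
            for a in r.atoms:
                a.coord = a.coord + np.array([6.0, 0.0, 0.0])
        core = (1, 20)
        sub = ev.subset_rmsd(disturbed, helix30, core, align_on="subset", mirror_aware=False)
        glob, _ = ev.global_rmsd(disturbed, helix30, mirror_aware=False)
        assert sub < glob

    def test_local_rmsd_native_all_zero(self, helix30):
        lr = ev.local_rmsd(helix30, helix30)
        assert lr.shape == (30,)
        assert np.allclose(lr, 0.0, atol=1e-6)

    def test_local_rmsd_flags_displaced_residue(self, helix30):
        disturbed = helix30.copy()
        res = list(disturbed.residues())
        for a in res[15].atoms:
            a.coord = a.coord + np.array([2.0, 0.0, 0.0])
        lr = ev.local_rmsd(disturbed, helix30)
        assert lr[15] == lr.max()
        assert lr[15] == pytest.approx(2.0, abs=0.5)

    def test_empty_selection_rejected(self, helix30):
        with pytest.raises(ValueError):
            ev.subset_rmsd(helix30, helix30, (500, 600))


class TestDiameter:
    def test_by_construction(self, tetramer14):
        marker = tetramer14.metadata["marker_seq_index"]
        d = ev.structure_diameter(tetramer14, marker, ("A", "C"))
        assert d == pytest.approx(2 * tetramer14.metadata["pore_radius"], abs=1e-9)

    def test_symmetry_pairs_equal(self, tetramer14):
        marker = tetramer14.metadata["marker_seq_index"]
        assert ev.structure_diameter(tetramer14, marker, ("A", "C")) == pytest.approx(
            ev.structure_diameter(tetramer14, marker, ("B", "D")), abs=1e-9
        )

    def test_matches_direct_subtraction(self, tetramer14):
        marker = tetramer14.metadata["marker_seq_index"]
        a = [r for r in tetramer14.chain("A").residues if r.seq_index == marker][0].atom("CA").coord
        c = [r for r in tetramer14.chain("C").residues if r.seq_index == marker][0].atom("CA").coord
        assert ev.structure_diameter(tetramer14, marker, ("A", "C")) == pytest.approx(
            float(np.linalg.norm(a - c))
        )

    def test_absent_residue(self, tetramer14):
        with pytest.raises(ValueError):
            ev.structure_diameter(tetramer14, 999, ("A", "C"))


def _brute_force_tau(x, y):
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


class TestKendall:
    def test_perfect_correlation(self):
        x = [1.0, 2, 3, 4, 5]
        assert ev.kendall_tau(x, x)[0] == pytest.approx(1.0)
        assert ev.kendall_tau(x, [-v for v in x])[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=6).astype(float)
        y = rng.integers(0, 4, size=6).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        tau, _ = ev.kendall_tau(x, y)
        assert tau == pytest.approx(_brute_force_tau(x, y), abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError):
            ev.kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRankSum:
    def test_identical_samples_z_near_zero(self):
        a = [1.0, 2, 3, 4, 5]
        z, p = ev.ranksum_test(a, a)
        assert abs(z) < 1e-9
        assert p == pytest.approx(1.0)

    def test_complete_separation_closed_form(self):
        # n = m = 10, all of a below b: rank sum of a = 55 (minimum)
        a = list(range(10))
        b = list(range(100, 110))
        z, p = ev.ranksum_test(a, b)
        mu = 10 * 21 / 2
        sigma = np.sqrt(10 * 10 * 21 / 12)
        assert z == pytest.approx((55 - mu) / sigma, abs=1e-12)

    def test_normal_approx_close_to_exact_permutation(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=8)
        b = rng.normal(loc=1.0, size=8)
        z, p = ev.ranksum_test(a, b)
        combined = np.concatenate([a, b])
        ranks = np.argsort(np.argsort(combined)) + 1.0
        observed = ranks[:8].sum()
        mu = 8 * 17 / 2
        count = total = 0
        for idx in itertools.combinations(range(16), 8):
            w = ranks[list(idx)].sum()
            total += 1
            count += abs(w - mu) >= abs(observed - mu) - 1e-12
        exact_p = count / total
        assert p == pytest.approx(exact_p, abs=0.02)
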