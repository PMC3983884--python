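"""Chirality, backbone completion and side-chain placement."""

import numpy as np
import pytest

from cmap2struct import allatom, evalmetrics
from cmap2struct.allatom import _dihedral
from cmap2struct.fixtures import helix_ca_points
from cmap2struct.structio import CaTrace, extract_ca_trace, read_pdb, write_pdb


def _mirror(points):
    out = np.asarray(points, float).copy()
    out[:, 0] *= -1
    return out


class TestChirality:
    def test_right_handed_helix_unchanged(self):
        tr = CaTrace(helix_ca_points(20))
        assert allatom.fix_chirality(tr) is tr

    def test_mirror_is_flipped_back(self):
        tr = CaTrace(helix_ca_points(20))
        mirrored = CaTrace(_mirror(tr.points))
        fixed = allatom.fix_chirality(mirrored)
        rmsd, used_mirror = evalmetrics.mirror_aware_rmsd(fixed.points, tr.points)
        assert not used_mirror
        _, _, direct = evalmetrics.kabsch_superpose(fixed.points, tr.points)
        assert direct == pytest.approx(0.0, abs=1e-5)

    def test_involution_on_mirror_pairs(self):
        tr = CaTrace(helix_ca_points(15))
        once = allatom.fix_chirality(CaTrace(_mirror(tr.points)))
        twice = allatom.fix_chirality(once)
        assert np.array_equal(once.points, twice.points)

    def test_short_trace_warns(self):
        tr = CaTrace(np.zeros((4, 3)))
        with pytest.warns(UserWarning):
            out = allatom.fix_chirality(tr)
        assert out is tr

    def test_noisy_mirrored_helices_mostly_restored(self):
        """Stochastic property: helical traces with 1 A coordinate noise
        and random reflection come back right-handed >= 95 % of the time."""
        native = helix_ca_points(30)
        rng = np.random.default_rng(0)
        correct = 0
        n = 100
        for _ in range(n):
            pts = native + rng.normal(scale=1.0, size=native.shape)
            if rng.random() < 0.5:
                pts = _mirror(pts)
            fixed = allatom.fix_chirality(CaTrace(pts))
            _, _, direct = evalmetrics.kabsch_superpose(fixed.points, native)
            _, _, refl = evalmetrics.kabsch_superpose(_mirror(fixed.points), native)
            correct += direct <= refl
        assert correct / n >= 0.95


class TestBackbone:
    def test_two_residue_trace(self):
        tr = CaTrace(np.array([[0.0, 0, 0], [3.8, 0, 0]]))
        s = allatom.build_backbone(tr, ["ALA", "ALA"])
        for r in s.residues():
            assert {"N", "CA", "C", "O"} <= set(r.atom_names)
        assert np.allclose(list(s.residues())[0].atom("CA").coord, [0, 0, 0])

    def test_helix_dihedrals_near_ideal(self):
        tr = CaTrace(helix_ca_points(12))
        s = allatom.build_backbone(tr, ["ALA"] * 12)
        res = list(s.residues())
        for i in range(2, 10):
            phi = _dihedral(res[i - 1].atom("C").coord, res[i].atom("N").coord,
                            res[i].atom("CA").coord, res[i].atom("C").coord)
            psi = _dihedral(res[i].atom("N").coord, res[i].atom("CA").coord,
                            res[i].atom("C").coord, res[i + 1].atom("N").coord)
            assert phi == pytest.approx(-57.0, abs=40.0)
            assert psi == pytest.approx(-47.0, abs=40.0)

    def test_ca_preserved_bit_exact(self):
        pts = helix_ca_points(10)
        s = allatom.build_backbone(CaTrace(pts), ["ALA"] * 10)
        got = np.array([r.atom("CA").coord for r in s.residues()])
        assert np.array_equal(got, pts)

    def test_native_backbone_recovery(self, helix30):
        """Rebuilding from the CA trace alone recovers the backbone closely."""
        tr = extract_ca_trace(helix30)
        rebuilt = allatom.build_backbone(tr, helix30.sequence())
        rmsd, _ = evalmetrics.global_rmsd(rebuilt, helix30, mirror_aware=False)
        assert rmsd < 1.0

    def test_bond_violation_rejected(self):
        tr = CaTrace(np.array([[0.0, 0, 0], [10.0, 0, 0], [13.8, 0, 0]]))
        with pytest.raises(ValueError, match="bond"):
            allatom.build_backbone(tr, ["ALA"] * 3)

    def test_pdb_round_trip(self, tmp_path):
        s = allatom.build_backbone(CaTrace(helix_ca_points(8)), ["ALA"] * 8)
        p = tmp_path / "bb.pdb"
        write_pdb(s, p)
        back = read_pdb(p)
        assert back.n_residues == 8
        assert np.allclose(back.coords(), s.coords(), atol=5e-4)


class TestSidechains:
    def test_polyalanine_gets_cb(self):
        s = allatom.build_backbone(CaTrace(helix_ca_points(8)), ["ALA"] * 8)
        full = allatom.place_sidechains(s)
        for r in full.residues():
            assert r.has_atom("CB")
            cb = r.atom("CB").coord
            assert np.linalg.norm(cb - r.atom("CA").coord) == pytest.approx(1.52, abs=0.1)

    def test_ca_never_moves(self):
        s = allatom.build_backbone(CaTrace(helix_ca_points(10)), ["ALA"] * 5 + ["LYS"] * 5)
        before = np.array([r.atom("CA").coord for r in s.residues()])
        full = allatom.relieve_clashes(allatom.place_sidechains(s))
        after = np.array([r.atom("CA").coord for r in full.residues()])
        assert np.array_equal(before, after)

    def test_lysine_open_space_gets_top_rotamer(self):
        pts = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0.5, 0], [11.0, 0, 1.0]])
        s = allatom.build_backbone(CaTrace(pts), ["ALA", "LYS", "ALA", "ALA"])
        full = allatom.place_sidechains(s)
        lys = list(full.residues())[1]
        chi1 = _dihedral(lys.atom("N").coord, lys.atom("CA").coord,
                         lys.atom("CB").coord, lys.atom("CG").coord)
        top = allatom.DEFAULT_ROTAMERS.rotamers("LYS")[0][1][0]
        assert chi1 == pytest.approx(top, abs=5.0)

    def test_placement_is_no_worse_than_any_single_rotamer(self):
        # two close antiparallel strands crowd the tryptophans
        pts = np.array([
            [0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0],
            [11.4, 4.6, 0], [7.6, 4.6, 0], [3.8, 4.6, 0], [0.0, 4.6, 0],
        ])
        s = allatom.build_backbone(CaTrace(pts), ["ALA", "TRP", "ALA", "ALA",
                                                  "ALA", "TRP", "ALA", "ALA"])
        full = allatom.place_sidechains(s)
        res5 = list(full.residues())[5]
        chosen = allatom._residue_clashes(5, full)
        backbone = {a: res5.atom(a).coord for a in ("N", "CA", "C")}
        counts = []
        for _, chis in allatom.DEFAULT_ROTAMERS.rotamers("TRP"):
            allatom._set_sidechain(res5, allatom._sidechain_coords("TRP", backbone, chis))
            counts.append(allatom._residue_clashes(5, full))
        assert chosen <= min(counts)

    def test_unknown_residue_warns_alanine(self):
        s = allatom.build_backbone(CaTrace(helix_ca_points(5)), ["ALA", "XYZ", "ALA", "ALA", "ALA"])
        with pytest.warns(UserWarning, match="XYZ"):
            full = allatom.place_sidechains(s)
        assert list(full.residues())[1].has_atom("CB")


class TestClashRelief:
    def test_clash_free_is_identity(self):
        s = allatom.place_sidechains(
            allatom.build_backbone(CaTrace(helix_ca_points(8)), ["ALA"] * 8)
        )
        assert allatom.count_clashes(s) == 0
        out = allatom.relieve_clashes(s)
        assert np.allclose(out.coords(), s.coords())

    def test_clash_count_monotone(self):
        pts = np.array([
            [0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0],
            [11.4, 4.6, 0], [7.6, 4.6, 0], [3.8, 4.6, 0], [0.0, 4.6, 0],
        ])
        seq = ["ALA", "LYS", "PHE", "ALA", "ALA", "GLU", "LEU", "ALA"]
        s = allatom.place_sidechains(allatom.build_backbone(CaTrace(pts), seq))
        before = allatom.count_clashes(s)
        out = allatom.relieve_clashes(s, max_iters=10)
        assert allatom.count_clashes(out) <= before
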