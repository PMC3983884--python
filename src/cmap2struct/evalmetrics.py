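"""Structural model-quality metrics.

Provides least-squares rigid superposition (Kabsch), global / subset /
per-residue heavy-atom RMSDs, the channel "structure diameter"
(distance between a marker residue of two opposite chains), and the
rank statistics used to relate structural and electrostatic quality
(Kendall tau-b, Wilcoxon rank-sum z).

Contact maps carry no handedness, and symmetric assemblies have no
canonical chain labelling, so the RMSD operations can minimize over
{identity, mirror} x cyclic chain permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .structio import Structure

__all__ = [
    "EvaluationReport",
    "kabsch_superpose",
    "mirror_aware_rmsd",
    "paired_atom_coords",
    "global_rmsd",
    "subset_rmsd",
    "local_rmsd",
    "structure_diameter",
    "kendall_tau",
    "ranksum_test",
]


@dataclass
class EvaluationReport:
    """Per-model quality summary."""

    global_rmsd: float
    filter_rmsd: Optional[float] = None
    local_rmsd: Optional[np.ndarray] = None
    diameter: Optional[float] = None
    cd: Optional[float] = None
    mirror_used: bool = False
    chain_permutation: int = 0
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired point sets.

    Returns ``(R, t, rmsd)`` such that ``R @ x + t`` maps ``mobile``
    onto ``target`` with least-squares optimal RMSD and ``det(R) = +1``.
    Fewer than 3 points fall back to a pure translation.
    """
    mobile = np.asarray(mobile, float).reshape(-1, 3)
    target = np.asarray(target, float).reshape(-1, 3)
    if mobile.shape != target.shape:
        raise ValueError(f"point sets differ in shape: {mobile.shape} vs {target.shape}")
    n = mobile.shape[0]
    cm, ct = mobile.mean(0), target.mean(0)
    if n < 3:
        t = ct - cm
        rmsd = float(np.sqrt(np.mean(np.sum((mobile + t - target) ** 2, axis=1))))
        return np.eye(3), t, rmsd
    import warnings

    with warnings.catch_warnings():
        # align_vectors warns when the optimum is not unique (planar or
        # symmetric sets); any minimizer is acceptable for an RMSD
        warnings.filterwarnings("ignore", message=".*Optimal rotation.*")
        rot, rssd = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    t = ct - R @ cm
    rmsd = float(rssd / np.sqrt(n))
    return R, t, rmsd


def mirror_aware_rmsd(mobile: np.ndarray, target: np.ndarray) -> tuple[float, bool]:
    """Minimum Kabsch RMSD over the point set and its reflection."""
    _, _, direct = kabsch_superpose(mobile, target)
    mirrored = np.asarray(mobile, float).copy()
    mirrored[:, 0] *= -1.0
    _, _, refl = kabsch_superpose(mirrored, target)
    return (direct, False) if direct <= refl else (refl, True)


# ---------------------------------------------------------------------------
# Atom pairing between model and native
# ---------------------------------------------------------------------------

def _pairing(model: Structure, native: Structure, chain_shift: int = 0):
    """Shared heavy atoms per residue, pairing chains by position.

    ``chain_shift`` cyclically rotates the model chains before pairing.
    Yields ``(res_pos, model_atom_coord, native_atom_coord)`` triples.
    """
    if len(model.chains) != len(native.chains):
        raise ValueError("model and native have different chain counts")
    nch = len(model.chains)
    order = [(k + chain_shift) % nch for k in range(nch)]
    pairs = []
    res_pos = 0
    for k, mk in enumerate(order):
        mres = model.chains[mk].residues
        nres = native.chains[k].residues
        if len(mres) != len(nres):
            raise ValueError("chain residue counts differ between model and native")
        for rm, rn in zip(mres, nres):
            shared = [a for a in rm.atom_names if rn.has_atom(a)]
            for name in shared:
                pairs.append((res_pos, rm.atom(name).coord, rn.atom(name).coord))
            res_pos += 1
    if not pairs:
        raise ValueError("no common atoms between model and native")
    idx = np.array([p[0] for p in pairs])
    xm = np.array([p[1] for p in pairs])
    xn = np.array([p[2] for p in pairs])
    return idx, xm, xn


def global_rmsd(
    model: Structure,
    native: Structure,
    mirror_aware: bool = True,
    permute_chains: bool = False,
) -> tuple[float, dict]:
    """Heavy-atom RMSD after optimal superposition.

    When the flags are set, the minimum over {identity, mirror} and over
    cyclic chain permutations is returned; the chosen combination is
    reported in the info dict.
    """
    nch = len(model.chains)
    shifts = range(nch) if permute_chains and nch > 1 else [0]
    best = None
    for shift in shifts:
        _, xm, xn = _pairing(model, native, chain_shift=shift)
        _, _, direct = kabsch_superpose(xm, xn)
        candidates = [(direct, False)]
        if mirror_aware:
            xm_ref = xm.copy()
            xm_ref[:, 0] *= -1.0
            _, _, refl = kabsch_superpose(xm_ref, xn)
            candidates.append((refl, True))
        for rmsd, mirrored in candidates:
            if best is None or rmsd < best[0]:
                best = (rmsd, mirrored, shift)
    return best[0], {"mirror_used": best[1], "chain_permutation": best[2]}


def _select_mask(structure: Structure, residue_selection) -> np.ndarray:
    """Boolean mask over concatenated residue positions.

    ``residue_selection`` is a ``(lo, hi)`` inclusive range of per-chain
    seq_index values (applied in every chain), or an explicit set of
    concatenated 1-based positions.
    """
    n = structure.n_residues
    mask = np.zeros(n, dtype=bool)
    if isinstance(residue_selection, tuple) and len(residue_selection) == 2:
        lo, hi = residue_selection
        for pos, r in enumerate(structure.residues()):
            if lo <= r.seq_index <= hi:
                mask[pos] = True
    else:
        for pos in residue_selection:
            mask[pos - 1] = True
    return mask


def subset_rmsd(
    model: Structure,
    native: Structure,
    residue_selection,
    align_on: str = "subset",
    mirror_aware: bool = True,
) -> float:
    """RMSD over a residue selection.

    ``align_on='subset'`` superposes on the selection atoms only (e.g.
    the selectivity-filter alignment); ``'global'`` superposes on all
    shared atoms first and then scores the selection.
    """
    sel_mask = _select_mask(native, residue_selection)
    if not sel_mask.any():
        raise ValueError("empty residue selection")
    idx, xm, xn = _pairing(model, native)
    in_sel = sel_mask[idx]
    if not in_sel.any():
        raise ValueError("selection matches no paired atoms")

    def _score(xm_arr):
        if align_on == "subset":
            _, _, r = kabsch_superpose(xm_arr[in_sel], xn[in_sel])
            return r
        R, t, _ = kabsch_superpose(xm_arr, xn)
        moved = xm_arr[in_sel] @ R.T + t
        return float(np.sqrt(np.mean(np.sum((moved - xn[in_sel]) ** 2, axis=1))))

    direct = _score(xm)
    if not mirror_aware:
        return direct
    xm_ref = xm.copy()
    xm_ref[:, 0] *= -1.0
    return min(direct, _score(xm_ref))


def local_rmsd(model: Structure, native: Structure, mirror_aware: bool = True) -> np.ndarray:
    """Per-residue heavy-atom RMSD after a single global superposition."""
    idx, xm, xn = _pairing(model, native)

    def _per_residue(xm_arr):
        R, t, _ = kabsch_superpose(xm_arr, xn)
        moved = xm_arr @ R.T + t
        sq = np.sum((moved - xn) ** 2, axis=1)
        n_res = int(idx.max()) + 1
        out = np.zeros(n_res)
        for pos in range(n_res):
            m = idx == pos
            out[pos] = np.sqrt(sq[m].mean()) if m.any() else np.nan
        return out

    direct = _per_residue(xm)
    if not mirror_aware:
        return direct
    _, _, d_rmsd = kabsch_superpose(xm, xn)
    xm_ref = xm.copy()
    xm_ref[:, 0] *= -1.0
    _, _, r_rmsd = kabsch_superpose(xm_ref, xn)
    return direct if d_rmsd <= r_rmsd else _per_residue(xm_ref)


def structure_diameter(
    structure: Structure,
    residue_number: int,
    chain_pair: tuple[str, str] = ("A", "C"),
    atom: str = "CA",
) -> float:
    """Distance between a marker residue's atom in two opposite chains."""
    coords = []
    for cid in chain_pair:
        ch = structure.chain(cid)
        matches = [r for r in ch.residues if r.seq_index == residue_number]
        if not matches:
            raise ValueError(f"chain {cid} has no residue {residue_number}")
        coords.append(matches[0].atom(atom).coord)
    return float(np.linalg.norm(coords[0] - coords[1]))


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall tau-b with tie correction and two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length vectors with >= 2 entries")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for a constant vector")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum z (tie-corrected normal approximation), two-sided p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie correction to the variance of the rank sum
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
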