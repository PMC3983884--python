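"""Calpha-trace reconstruction from a ternary contact map.

The reconstructor is a two-phase, seeded stochastic scheme:

1. *Initialization* — a self-avoiding-ish random walk with virtual
   Calpha-Calpha bonds, biased toward a compact ball whose radius scales
   as L^(1/3) (globular packing).
2. *Refinement* — iterative constraint projection.  Each sweep computes
   all pairwise distances and corrects violated restraints: contacting
   pairs further apart than the threshold are pulled together, known
   non-contacts inside the threshold are pushed just beyond it, and
   bonded neighbours are reset to the virtual bond length.  When the
   restraint-satisfaction score stagnates, the coordinates are jittered
   with Gaussian noise and refinement continues from the best structure
   seen so far.

Unknown (-1) pairs impose no force and do not count toward
satisfaction.  Contact maps carry no chirality information, so a
refined trace may be the mirror image of the target; handedness is
resolved downstream (:func:`cmap2struct.allatom.fix_chirality`), and
model assessment uses mirror-aware RMSDs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cmap import ContactMap
from .structio import CaTrace

__all__ = [
    "CaTrace",
    "ReconConfig",
    "initialize_trace",
    "refine_trace",
    "reconstruct_ca",
    "contact_satisfaction",
]


@dataclass
class ReconConfig:
    """Tunable parameters of the trace reconstructor (Angstrom units)."""

    bond_length: float = 3.8
    contact_threshold: float = 8.0
    max_sweeps: int = 500
    satisfaction_target: float = 0.98
    restart_count: int = 3
    perturb_sigma: float = 1.0
    move_fraction: float = 1.0
    noncontact_margin: float = 0.1
    stall_sweeps: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.bond_length, self.contact_threshold, self.max_sweeps,
               self.restart_count, self.perturb_sigma) <= 0:
            raise ValueError("all reconstruction parameters must be positive")
        if not 0.0 < self.satisfaction_target <= 1.0:
            raise ValueError("satisfaction_target must be in (0, 1]")


def _pair_indices(cmap: ContactMap, chain_breaks: frozenset[int]):
    """Split upper-triangle pairs into bond / contact / non-contact sets."""
    L = cmap.L
    iu, ju = np.triu_indices(L, k=1)
    labels = cmap.matrix[iu, ju]
    adjacent = ju == iu + 1
    broken = np.isin(iu, list(chain_breaks)) if chain_breaks else np.zeros_like(adjacent)
    bonded = adjacent & ~broken
    contact = (labels == 1) & ~bonded
    noncontact = (labels == 0) & ~bonded
    return iu, ju, bonded, contact, noncontact


def initialize_trace(cmap: ContactMap, config: ReconConfig) -> CaTrace:
    """Seeded compact random walk with virtual-bond steps."""
    rng = np.random.default_rng(config.seed)
    L = cmap.L
    radius = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0) * L ** (1.0 / 3.0) * 4.0
    pts = np.zeros((L, 3))
    x = rng.normal(size=3) * radius / 4.0
    pts[0] = x
    for i in range(1, L):
        step = rng.normal(size=3)
        step /= np.linalg.norm(step)
        r = np.linalg.norm(x)
        if r > 1e-9:
            # pull back toward the ball once the walk strays outside it
            bias = min(r / radius, 2.0)
            step = step - bias * (x / r)
            step /= np.linalg.norm(step)
        x = x + config.bond_length * step
        pts[i] = x
    return CaTrace(points=pts, chain_breaks=frozenset(), provenance={"seed": config.seed})


def contact_satisfaction(trace: CaTrace, cmap: ContactMap) -> float:
    """Fraction of known off-diagonal pairs whose distance matches its label.

    An all-unknown map is vacuously satisfied (returns 1.0).
    """
    if len(trace) != cmap.L:
        raise ValueError(f"trace length {len(trace)} != map size {cmap.L}")
    iu, ju = np.triu_indices(cmap.L, k=1)
    labels = cmap.matrix[iu, ju]
    known = labels != -1
    if not known.any():
        return 1.0
    d = np.linalg.norm(trace.points[iu[known]] - trace.points[ju[known]], axis=1)
    lab = labels[known]
    thr = float(cmap.meta.get("threshold", 8.0))
    ok = np.where(lab == 1, d <= thr, d > thr)
    return float(np.mean(ok))


def _sweep(X, iu, ju, bonded, contact, noncontact, cfg: ReconConfig):
    """One Jacobi constraint-projection sweep, in place."""
    L = X.shape[0]
    diff = X[iu] - X[ju]
    d = np.linalg.norm(diff, axis=1)
    np.maximum(d, 1e-9, out=d)
    thr = cfg.contact_threshold

    disp = np.zeros_like(X)
    counts = np.zeros(L)

    def _accumulate(mask, target):
        if not mask.any():
            return
        i, j = iu[mask], ju[mask]
        # scale so that applying the correction to both ends reaches `target`
        s = 0.5 * cfg.move_fraction * (1.0 - target / d[mask])
        delta = s[:, None] * diff[mask]
        np.add.at(disp, i, -delta)
        np.add.at(disp, j, delta)
        np.add.at(counts, i, 1.0)
        np.add.at(counts, j, 1.0)

    viol_contact = contact & (d > thr)
    viol_non = noncontact & (d <= thr)
    _accumulate(viol_contact, thr * 0.95)
    _accumulate(viol_non, thr + cfg.noncontact_margin)
    X += disp / np.maximum(counts, 1.0)[:, None]

    # bond constraints enforced harder: a few Jacobi passes to near-exactness
    bi, bj = iu[bonded], ju[bonded]
    for _ in range(4):
        bdiff = X[bi] - X[bj]
        bd = np.linalg.norm(bdiff, axis=1)
        np.maximum(bd, 1e-9, out=bd)
        corr = 0.5 * (1.0 - cfg.bond_length / bd)[:, None] * bdiff
        bdisp = np.zeros_like(X)
        bcounts = np.zeros(L)
        np.add.at(bdisp, bi, -corr)
        np.add.at(bdisp, bj, corr)
        np.add.at(bcounts, bi, 1.0)
        np.add.at(bcounts, bj, 1.0)
        X += bdisp / np.maximum(bcounts, 1.0)[:, None]
    return int(viol_contact.sum() + viol_non.sum())


def refine_trace(trace: CaTrace, cmap: ContactMap, config: ReconConfig) -> CaTrace:
    """Refine a trace until the restraints are satisfied or sweeps run out.

    Returns the best-ever trace (highest satisfaction), with the sweep
    count and final satisfaction recorded in ``provenance``.
    """
    if len(trace) != cmap.L:
        raise ValueError(f"trace length {len(trace)} != map size {cmap.L}")
    cfg = replace(config, contact_threshold=float(cmap.meta.get("threshold", config.contact_threshold)))
    rng = np.random.default_rng((cfg.seed, 0x5EED))
    iu, ju, bonded, contact, noncontact = _pair_indices(cmap, trace.chain_breaks)

    X = trace.points.copy()
    best_X = X.copy()
    best_sat = contact_satisfaction(trace, cmap)
    stall = 0
    sweeps_used = 0
    for sweep in range(cfg.max_sweeps):
        sweeps_used = sweep + 1
        _sweep(X, iu, ju, bonded, contact, noncontact, cfg)
        sat = contact_satisfaction(CaTrace(X, trace.chain_breaks), cmap)
        if sat > best_sat:
            best_sat = sat
            best_X = X.copy()
            stall = 0
        else:
            stall += 1
        if best_sat >= cfg.satisfaction_target:
            break
        if stall >= cfg.stall_sweeps:
            X = best_X + rng.normal(scale=cfg.perturb_sigma, size=X.shape)
            stall = 0
    prov = dict(trace.provenance)
    prov.update({"sweeps": sweeps_used, "satisfaction": best_sat})
    return CaTrace(points=best_X, chain_breaks=trace.chain_breaks, provenance=prov)


def _single_run(cmap: ContactMap, config: ReconConfig) -> CaTrace:
    best = None
    for restart in range(config.restart_count):
        cfg = replace(config, seed=int(np.random.SeedSequence((config.seed, restart)).generate_state(1)[0] % 2**31))
        init = initialize_trace(cmap, cfg)
        refined = refine_trace(init, cmap, cfg)
        if best is None or refined.provenance["satisfaction"] > best.provenance["satisfaction"]:
            best = refined
        if best.provenance["satisfaction"] >= config.satisfaction_target:
            break
    best.provenance["seed"] = config.seed
    return best


def reconstruct_ca(cmap: ContactMap, config: ReconConfig, n_models: int = 1) -> list[CaTrace]:
    """Generate an ensemble of reconstructed traces (seeds seed, seed+1, ...).

    Dummy positions (if any) take part in chain bonding but impose no
    contact restraints (their rows are entirely unknown by construction).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return [_single_run(cmap, replace(config, seed=config.seed + k)) for k in range(n_models)]
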