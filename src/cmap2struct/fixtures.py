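"""Deterministic synthetic structures and toy systems.

Everything downstream — map derivation, trace reconstruction, symmetry
assembly, electrostatics — is testable on these generators without any
external structure files: an ideal alpha-helix, a beta-hairpin-like
chain, a compact random coil, a C4-symmetric toy channel with a pore,
and a +/- point-charge pair for the Poisson solver.

Fixtures are poly-alanine except designated charged residues, keeping
side-chain placement trivial in pipeline tests.  All generators are
reproducible given their arguments (and seed where applicable).
"""

from __future__ import annotations

import numpy as np

from .allatom import build_backbone, place_sidechains
from .electro import PointCharge
from .structio import CaTrace, Structure

__all__ = [
    "helix_ca_points",
    "make_ideal_helix",
    "make_hairpin",
    "make_compact_coil",
    "make_toy_tetramer",
    "make_charge_pair",
]

#: ideal alpha-helix Calpha geometry
HELIX_RISE = 1.5  # Angstrom per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Angstrom


def helix_ca_points(n: int, rise: float = HELIX_RISE, twist: float = HELIX_TWIST,
                    radius: float = HELIX_RADIUS) -> np.ndarray:
    """Right-handed helical Calpha coordinates, axis on z through origin."""
    k = np.arange(n)
    ang = np.radians(twist * k)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * k])


def make_ideal_helix(n: int = 30) -> Structure:
    """Poly-alanine ideal alpha-helix completed to an N/CA/C/O backbone."""
    if n < 4:
        raise ValueError("need at least 4 residues")
    trace = CaTrace(helix_ca_points(n), provenance={"fixture": "ideal_helix"})
    return build_backbone(trace, ["ALA"] * n)


def make_hairpin(n: int = 40) -> Structure:
    """Two antiparallel extended strands joined by a tight turn."""
    if n < 8:
        raise ValueError("need at least 8 residues")
    n1 = n // 2
    rise = 3.4  # extended-strand Calpha spacing along the strand axis
    sep = 5.0  # inter-strand distance
    pts = []
    for i in range(n1):
        pts.append([0.45 * (-1) ** i, 1.2 * (-1) ** i, rise * i])
    turn_z = rise * (n1 - 1)
    for j, i in enumerate(range(n1, n)):
        pts.append([sep + 0.45 * (-1) ** i, -1.2 * (-1) ** i, turn_z - rise * j])
    pts = np.asarray(pts, float)
    # rescale consecutive steps to the virtual bond length
    out = [pts[0]]
    for i in range(1, len(pts)):
        step = pts[i] - pts[i - 1]
        out.append(out[-1] + step / np.linalg.norm(step) * 3.8)
    trace = CaTrace(np.array(out), provenance={"fixture": "hairpin"})
    return build_backbone(trace, ["ALA"] * n)


def make_compact_coil(n: int = 60, seed: int = 0) -> Structure:
    """Seeded compact self-avoiding-ish random walk, poly-alanine."""
    rng = np.random.default_rng(seed)
    radius = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0) * n ** (1.0 / 3.0) * 4.0
    pts = [np.zeros(3)]
    while len(pts) < n:
        best = None
        for _ in range(60):  # rejection sampling with a bounded budget
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            x = pts[-1]
            r = np.linalg.norm(x)
            if r > 1e-9:
                step = step - min(r / radius, 2.0) * x / r
                step /= np.linalg.norm(step)
            cand = x + 3.8 * step
            clearance = (
                float(np.min(np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)))
                if len(pts) > 1 else np.inf
            )
            if clearance >= 3.5:
                best = cand
                break
            if best is None or clearance > best[1]:
                best = (cand, clearance)
        pts.append(best if isinstance(best, np.ndarray) else best[0])
    trace = CaTrace(np.array(pts), provenance={"fixture": "compact_coil", "seed": seed})
    return build_backbone(trace, ["ALA"] * n)


def make_toy_tetramer(n_per_chain: int = 20, pore_radius: float = 5.0) -> Structure:
    """Four helical chains in exact C4 symmetry about z around a pore.

    Each chain is an ideal helix whose axis is parallel to z at distance
    ``pore_radius + HELIX_RADIUS`` from the pore axis, so the marker
    residue (the one whose Calpha points straight at the pore axis,
    stored in ``metadata['marker_seq_index']``) sits at radius
    ``pore_radius`` exactly and opposite-chain markers are
    ``2 * pore_radius`` apart.
    """
    if n_per_chain < 10:
        raise ValueError("need at least 10 residues per chain")
    base = helix_ca_points(n_per_chain)
    # marker: residue whose CA azimuth points toward -x (the pore axis side)
    k = np.arange(n_per_chain)
    ang = np.radians(HELIX_TWIST * k)
    marker = int(np.argmin(np.cos(ang)[3:-3])) + 3  # interior residue closest to angle pi
    offset = pore_radius + HELIX_RADIUS * float(-np.cos(np.radians(HELIX_TWIST * marker)))
    base = base + np.array([offset, 0.0, -HELIX_RISE * (n_per_chain - 1) / 2.0])

    chains_pts = []
    for kk in range(4):
        th = np.pi / 2.0 * kk
        R = np.array([[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]])
        chains_pts.append(base @ R.T)
    pts = np.vstack(chains_pts)
    breaks = frozenset(n_per_chain * (kk + 1) - 1 for kk in range(3))
    trace = CaTrace(pts, chain_breaks=breaks, provenance={"fixture": "toy_tetramer"})
    # outward-facing charged rings (one aspartate, one lysine, at
    # different heights) give the pore a smooth mV-scale potential
    # profile dominated by well-constrained interior residues — the
    # functional signature probed by the axial-profile metrics; the
    # pore-facing marker residue stays alanine (diameter gauge)
    outward = np.where(np.cos(ang)[3:-3] > 0.5)[0] + 3
    if len(outward) < 2:
        outward = np.argsort(-np.cos(ang)[3:-3])[:2] + 3
    asp, lys = int(outward[-1]), int(outward[0])
    seq = ["ALA"] * n_per_chain
    seq[asp] = "ASP"
    seq[lys] = "LYS"
    struct = build_backbone(trace, seq * 4)
    struct = place_sidechains(struct)
    struct.metadata.update(
        {"fixture": "toy_tetramer", "marker_seq_index": marker + 1, "pore_radius": pore_radius}
    )
    return struct


def make_charge_pair(separation: float = 10.0) -> list[PointCharge]:
    """+1 e / -1 e on the z axis, symmetric about the origin."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    half = separation / 2.0
    return [PointCharge((0.0, 0.0, half), 1.0), PointCharge((0.0, 0.0, -half), -1.0)]
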