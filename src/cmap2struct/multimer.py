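"""Homomultimer assembly: dummy trimming, axis alignment, Cn projection.

A reconstructed multimer trace still contains the dummy-loop points
that separated the chains in the contact map; :func:`trim_dummy`
removes them and records chain breaks.  The channel is then oriented
with its pore axis on z (:func:`align_axis_to_z`), and each subunit is
projected ``n`` times about the axis (:func:`c_n_project`) to produce
exactly Cn-symmetric channels — ``order`` of them, one per subunit,
plus one from the averaged subunit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evalmetrics import kabsch_superpose
from .structio import CaTrace, Chain, Residue, Atom, Structure

__all__ = [
    "SymmetryFrame",
    "trim_dummy",
    "align_axis_to_z",
    "c_n_project",
    "average_subunit",
    "assemble_channels",
    "estimate_symmetry_frame",
]


@dataclass
class SymmetryFrame:
    """Cyclic symmetry: rotation axis, center and order."""

    axis: np.ndarray
    center: np.ndarray
    order: int = 4

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, float)
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise ValueError("axis must be non-zero")
        self.axis = self.axis / norm
        self.center = np.asarray(self.center, float)
        if self.order < 2:
            raise ValueError("symmetry order must be >= 2")


def trim_dummy(trace: CaTrace, mapping: dict[int, int]) -> CaTrace:
    """Drop dummy points from a trace reconstructed on an augmented map.

    ``mapping`` is the original->augmented 1-based index map returned by
    :func:`cmap2struct.cmap.insert_dummy_loops`; chain breaks are
    recorded wherever a dummy loop was removed.
    """
    if not mapping:
        raise ValueError("empty index mapping")
    if max(mapping.values()) > len(trace):
        raise ValueError(f"mapping refers to index {max(mapping.values())} beyond trace length {len(trace)}")
    order = sorted(mapping.items())
    keep = [new - 1 for _, new in order]
    points = trace.points[keep]
    breaks = set()
    for k in range(len(keep) - 1):
        if keep[k + 1] != keep[k] + 1:  # a dummy loop was excised here
            breaks.add(k)
    prov = dict(trace.provenance)
    prov["trimmed_dummies"] = len(trace) - len(keep)
    return CaTrace(points=points, chain_breaks=frozenset(breaks), provenance=prov)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.asarray(axis, float) * angle).as_matrix()


def _chain_centroids(structure: Structure) -> np.ndarray:
    cents = []
    for ch in structure.chains:
        coords = np.array([a.coord for r in ch.residues for a in r.atoms])
        cents.append(coords.mean(0))
    return np.array(cents)


def estimate_symmetry_frame(structure: Structure, order: int = 4) -> SymmetryFrame:
    """Symmetry frame from chain centroids: axis = normal of their best-fit plane."""
    cents = _chain_centroids(structure)
    if len(cents) < 3:
        raise ValueError("need >= 3 chains to estimate a symmetry axis")
    center = cents.mean(0)
    centered = cents - center
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8:
        raise ValueError("degenerate geometry: chain centroids are collinear")
    axis = vt[2]
    if axis[2] < 0:
        axis = -axis
    return SymmetryFrame(axis=axis, center=center, order=order)


def align_axis_to_z(structure: Structure, reference: Structure | None = None) -> Structure:
    """Orient the channel so its pore axis lies on z, centroid at origin.

    With a reference (assumed z-aligned), the structure is Kabsch-
    superposed onto it.  Otherwise the axis is estimated from the chain
    centroids and rotated onto z.
    """
    if reference is not None:
        coords_m = structure.coords()
        coords_r = reference.coords()
        if coords_m.shape != coords_r.shape:
            raise ValueError("structure/reference atom counts differ; supply matching structures")
        R, t, _ = kabsch_superpose(coords_m, coords_r)
        return structure.transformed(R, t)
    frame = estimate_symmetry_frame(structure, order=max(2, len(structure.chains)))
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(frame.axis, z)
    c = float(frame.axis @ z)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    t = -R @ frame.center
    out = structure.transformed(R, t)
    # canonical axial orientation: chain N-terminal halves below C-terminal
    # halves (the axis sign is otherwise arbitrary, which would randomize
    # any z-dependent comparison such as the pore potential profile)
    first, second = [], []
    for ch in out.chains:
        n = len(ch.residues)
        for k, r in enumerate(ch.residues):
            if r.has_atom("CA"):
                (first if k < n // 2 else second).append(r.atom("CA").coord[2])
    if first and second and np.mean(first) > np.mean(second):
        out = out.transformed(np.diag([1.0, -1.0, -1.0]), np.zeros(3))
    return out


def c_n_project(subunit: Structure, frame: SymmetryFrame) -> Structure:
    """Replicate a single-chain subunit n times about the symmetry axis."""
    if len(subunit.chains) != 1:
        raise ValueError(f"subunit must be a single chain, got {len(subunit.chains)}")
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = Structure(metadata=dict(subunit.metadata))
    for k in range(frame.order):
        R = _rotation_about(frame.axis, 2.0 * np.pi * k / frame.order)
        t = frame.center - R @ frame.center
        copy_k = subunit.transformed(R, t)
        ch = copy_k.chains[0]
        ch.chain_id = chain_ids[k]
        for r in ch.residues:
            r.chain_id = ch.chain_id
        out.chains.append(ch)
    return out


def average_subunit(subunits: list[Structure]) -> Structure:
    """Atom-wise average after superposing every subunit onto the first."""
    if not subunits:
        raise ValueError("no subunits given")
    ref = subunits[0]
    ref_coords = ref.coords()
    stacked = [ref_coords]
    names0 = [a.name for r in ref.residues() for a in r.atoms]
    for s in subunits[1:]:
        names = [a.name for r in s.residues() for a in r.atoms]
        if names != names0:
            raise ValueError("subunit atom sets differ; cannot average")
        R, t, _ = kabsch_superpose(s.coords(), ref_coords)
        stacked.append(s.coords() @ R.T + t)
    mean = np.mean(stacked, axis=0)
    out = ref.copy()
    i = 0
    for r in out.residues():
        for a in r.atoms:
            a.coord = mean[i]
            i += 1
    return out


def assemble_channels(per_chain_models: list[Structure], frame: SymmetryFrame) -> list[Structure]:
    """One Cn channel per subunit plus one from the averaged subunit."""
    if len(per_chain_models) != frame.order:
        raise ValueError(f"need {frame.order} subunits, got {len(per_chain_models)}")
    channels = [c_n_project(s, frame) for s in per_chain_models]
    channels.append(c_n_project(average_subunit(per_chain_models), frame))
    return [align_axis_to_z(c) for c in channels]
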