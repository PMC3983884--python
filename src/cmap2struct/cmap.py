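"""Ternary residue-residue contact maps and their perturbations.

A contact map is a symmetric L x L matrix over {1, 0, -1}: 1 marks a
contact (pair of residues within a distance threshold), 0 a known
non-contact, and -1 an *unknown* pair that imposes no restraint during
reconstruction.  The diagonal is a self-contact and is excluded from all
counts, reductions and flips.

The perturbation operations emulate degraded contact knowledge:

``positive_only``
    erase all non-contact information (every 0 becomes -1);
``reduce_cmap``
    keep a random fraction of known entries, the rest become unknown;
``inject_errors``
    flip a random fraction of entries to the opposite label.

``insert_dummy_loops`` separates the chains of a multimer map with
blocks of all-unknown rows/columns ("dummy amino acids") so that the
chain-continuity assumption of the trace reconstructor does not glue
chain termini together.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

__all__ = [
    "ContactMap",
    "PerturbationSpec",
    "derive_cmap",
    "contact_density",
    "positive_only",
    "reduce_cmap",
    "inject_errors",
    "insert_dummy_loops",
    "read_cmap",
    "write_cmap",
]


def _round_half_away(x: float) -> int:
    """Round half away from zero (symmetric counting rule)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class ContactMap:
    """Symmetric ternary contact matrix plus chain bookkeeping."""

    matrix: np.ndarray
    chain_layout: list[tuple[str, int]] = field(default_factory=list)
    dummy_mask: np.ndarray = None  # bool, length L; True at dummy positions
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"contact matrix must be square, got {M.shape}")
        if not np.isin(M, (-1, 0, 1)).all():
            bad = np.unique(M[~np.isin(M, (-1, 0, 1))])
            raise ValueError(f"contact matrix entries must be in {{1, 0, -1}}, found {bad}")
        if not np.array_equal(M, M.T):
            raise ValueError("contact matrix must be symmetric")
        M = M.astype(np.int8).copy()
        np.fill_diagonal(M, 1)
        self.matrix = M
        if self.dummy_mask is None:
            self.dummy_mask = np.zeros(self.L, dtype=bool)
        else:
            self.dummy_mask = np.asarray(self.dummy_mask, dtype=bool)
            if self.dummy_mask.shape != (self.L,):
                raise ValueError("dummy_mask length mismatch")
        if not self.chain_layout:
            self.chain_layout = [("A", int(self.L - self.dummy_mask.sum()))]
        n_real = sum(n for _, n in self.chain_layout)
        if n_real + int(self.dummy_mask.sum()) != self.L:
            raise ValueError("chain_layout lengths + dummy count must equal L")

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_chains(self) -> int:
        return len(self.chain_layout)

    def known_fraction(self) -> float:
        iu = np.triu_indices(self.L, k=1)
        vals = self.matrix[iu]
        return float(np.mean(vals != -1)) if vals.size else 1.0

    def counts(self) -> dict[int, int]:
        """Upper-triangle label counts (diagonal excluded)."""
        iu = np.triu_indices(self.L, k=1)
        vals = self.matrix[iu]
        return {lab: int(np.sum(vals == lab)) for lab in (1, 0, -1)}

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.matrix.copy(), list(self.chain_layout), self.dummy_mask.copy(), dict(self.meta)
        )


@dataclass
class PerturbationSpec:
    """Declarative description of one map-degradation experiment arm."""

    kind: Literal["complete", "positive_only", "reduce", "erroneous"]
    fraction: float = 1.0
    error_mode: Literal["flip_ones", "flip_both"] = "flip_ones"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")

    def apply(self, cmap: ContactMap, seed: Optional[int] = None) -> ContactMap:
        seed = self.seed if seed is None else seed
        if self.kind == "complete":
            return cmap.copy()
        if self.kind == "positive_only":
            return positive_only(cmap)
        if self.kind == "reduce":
            return reduce_cmap(cmap, self.fraction, seed)
        if self.kind == "erroneous":
            return inject_errors(cmap, self.fraction, self.error_mode, seed)
        raise ValueError(f"unknown perturbation kind {self.kind!r}")

    def label(self) -> str:
        if self.kind in ("complete", "positive_only"):
            return self.kind
        return f"{self.kind}_{int(round(self.fraction * 100))}"


# ---------------------------------------------------------------------------
# Derivation and density
# ---------------------------------------------------------------------------

def derive_cmap(structure, threshold: float = 8.0, atom_mode: str = "CA") -> ContactMap:
    """Derive a binary contact map from a structure.

    Two residues are in contact when their ``atom_mode`` atoms (CB falls
    back to CA for glycine or when CB is absent) lie within ``threshold``
    Angstrom.  All sequence separations are considered.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if atom_mode not in ("CA", "CB"):
        raise ValueError("atom_mode must be 'CA' or 'CB'")
    coords = []
    for r in structure.residues():
        name = atom_mode
        if atom_mode == "CB" and not r.has_atom("CB"):
            name = "CA"
        coords.append(r.atom(name).coord)
    X = np.asarray(coords, float)
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(-1))
    M = (D <= threshold).astype(np.int8)
    return ContactMap(
        matrix=M,
        chain_layout=structure.chain_layout,
        meta={"threshold": float(threshold), "atom_mode": atom_mode},
    )


def contact_density(cmap: ContactMap) -> float:
    """Average number of contacts per residue: CD = (1/L) sum_i c_i.

    ``c_i`` counts off-diagonal 1-entries in row i; unknown entries do
    not contribute.  Dummy rows/columns are excluded entirely.
    """
    keep = ~cmap.dummy_mask
    M = cmap.matrix[np.ix_(keep, keep)]
    L = M.shape[0]
    if L == 0:
        raise ValueError("empty contact map")
    c = (M == 1).sum(axis=1) - 1  # subtract the diagonal self-contact
    return float(c.sum() / L)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def positive_only(cmap: ContactMap) -> ContactMap:
    """Erase non-contact knowledge: every 0 becomes -1, 1s preserved."""
    out = cmap.copy()
    out.matrix[out.matrix == 0] = -1
    out.meta = {**out.meta, "perturbation": "positive_only"}
    return out


def _upper_known(cmap: ContactMap, labels: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(cmap.L, k=1)
    mask = np.isin(cmap.matrix[iu, ju], labels)
    return iu[mask], ju[mask]


def reduce_cmap(cmap: ContactMap, fraction: float, seed: int) -> ContactMap:
    """Keep a random ``fraction`` of known entries; the rest become -1.

    Exactly ``round((1 - fraction) * K)`` of the K known off-diagonal
    upper-triangle entries are unknown-ed (mirrored to the lower
    triangle); selection is uniform without replacement and reproducible
    for a given seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    out = cmap.copy()
    iu, ju = _upper_known(cmap, (0, 1))
    K = iu.size
    n_drop = _round_half_away((1.0 - fraction) * K)
    rng = np.random.default_rng(seed)
    sel = rng.choice(K, size=n_drop, replace=False)
    out.matrix[iu[sel], ju[sel]] = -1
    out.matrix[ju[sel], iu[sel]] = -1
    out.meta = {**out.meta, "perturbation": f"reduce_{fraction}", "seed": seed}
    return out


def inject_errors(
    cmap: ContactMap, fraction_correct: float, mode: str = "flip_ones", seed: int = 0
) -> ContactMap:
    """Flip a random fraction of entries to the opposite label.

    ``flip_ones``: ``round((1 - fraction_correct) * N1)`` of the
    upper-triangle 1-entries become 0.  ``flip_both``: the same count
    over *all* known entries, each flipped 1 <-> 0.  Mirrored; seeded.
    """
    if not 0.0 <= fraction_correct <= 1.0:
        raise ValueError("fraction_correct must be in [0, 1]")
    if mode not in ("flip_ones", "flip_both"):
        raise ValueError(f"invalid mode {mode!r}")
    out = cmap.copy()
    labels = (1,) if mode == "flip_ones" else (0, 1)
    iu, ju = _upper_known(cmap, labels)
    n_flip = _round_half_away((1.0 - fraction_correct) * iu.size)
    rng = np.random.default_rng(seed)
    sel = rng.choice(iu.size, size=n_flip, replace=False)
    fi, fj = iu[sel], ju[sel]
    flipped = (1 - out.matrix[fi, fj]).astype(np.int8)  # 1 <-> 0
    out.matrix[fi, fj] = flipped
    out.matrix[fj, fi] = flipped
    out.meta = {**out.meta, "perturbation": f"erroneous_{fraction_correct}_{mode}", "seed": seed}
    return out


# ---------------------------------------------------------------------------
# Dummy loops
# ---------------------------------------------------------------------------

def insert_dummy_loops(cmap: ContactMap, loop_length: int = 15) -> tuple[ContactMap, dict[int, int]]:
    """Insert all-unknown dummy rows/columns between consecutive chains.

    Returns the augmented map and an invertible mapping from original
    1-based concatenated indices to augmented 1-based indices.
    """
    if loop_length < 1:
        raise ValueError("loop_length must be >= 1")
    if cmap.dummy_mask.any():
        raise ValueError("map already contains dummy positions")
    if cmap.n_chains < 2:
        warnings.warn("single-chain map: dummy-loop insertion is a no-op", stacklevel=2)
        return cmap.copy(), {i + 1: i + 1 for i in range(cmap.L)}

    lengths = [n for _, n in cmap.chain_layout]
    n_loops = cmap.n_chains - 1
    L_new = cmap.L + loop_length * n_loops
    M_new = np.full((L_new, L_new), -1, dtype=np.int8)
    dummy = np.ones(L_new, dtype=bool)

    mapping: dict[int, int] = {}
    new_positions = []
    pos_old, pos_new = 0, 0
    for k, n in enumerate(lengths):
        for _ in range(n):
            mapping[pos_old + 1] = pos_new + 1
            new_positions.append(pos_new)
            dummy[pos_new] = False
            pos_old += 1
            pos_new += 1
        if k < n_loops:
            pos_new += loop_length
    new_positions = np.asarray(new_positions)
    M_new[np.ix_(new_positions, new_positions)] = cmap.matrix
    np.fill_diagonal(M_new, 1)
    out = ContactMap(
        matrix=M_new,
        chain_layout=list(cmap.chain_layout),
        dummy_mask=dummy,
        meta={**cmap.meta, "dummy_loop_length": loop_length},
    )
    return out, mapping


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_cmap(cmap: ContactMap, path, format: str = "matrix") -> None:
    """Write a map as a whitespace matrix or a CASP-RR-style pair list."""
    if format == "matrix":
        np.savetxt(path, cmap.matrix, fmt="%d")
    elif format == "rr_list":
        with open(path, "w") as fh:
            fh.write(f"# L={cmap.L}\n")
            iu, ju = np.triu_indices(cmap.L, k=1)
            vals = cmap.matrix[iu, ju]
            known = vals != -1
            for i, j, v in zip(iu[known] + 1, ju[known] + 1, vals[known]):
                fh.write(f"{i} {j} {v}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cmap(path, format: str = "matrix", L: Optional[int] = None) -> ContactMap:
    """Read a map written by :func:`write_cmap`.

    ``rr_list`` lines are 1-based ``i j label`` triplets over the upper
    triangle; unlisted pairs default to unknown.  A ``# L=<n>`` header
    (or explicit ``L``) gives the size.
    """
    if format == "matrix":
        M = np.loadtxt(path, dtype=float)
        M = np.atleast_2d(M)
        if M.shape[0] != M.shape[1]:
            raise ValueError(f"{path}: matrix is not square ({M.shape})")
        if not np.isin(M, (-1, 0, 1)).all():
            raise ValueError(f"{path}: entries outside {{1, 0, -1}}")
        if not np.array_equal(M, M.T):
            raise ValueError(f"{path}: asymmetric contact matrix")
        return ContactMap(M.astype(np.int8))
    if format == "rr_list":
        header_L = None
        triplets = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "L=" in line:
                        header_L = int(line.split("L=")[1].split()[0])
                    continue
                parts = line.split()
                triplets.append((int(parts[0]), int(parts[1]), int(parts[2])))
        size = L or header_L
        if size is None:
            size = max(max(i, j) for i, j, _ in triplets)
        M = np.full((size, size), -1, dtype=np.int8)
        for i, j, v in triplets:
            if v not in (0, 1):
                raise ValueError(f"{path}: rr_list label must be 0 or 1, got {v}")
            M[i - 1, j - 1] = v
            M[j - 1, i - 1] = v
        np.fill_diagonal(M, 1)
        return ContactMap(M)
    raise ValueError(f"unknown format {format!r}")
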