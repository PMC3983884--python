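"""Pore electrostatics: two-dielectric Poisson solve and axial profiles.

The functional quality of a channel model is probed by the
electrostatic potential along the pore axis.  With zero ionic strength
and zero membrane potential the linearized Poisson-Boltzmann equation
reduces to the variable-dielectric Poisson equation

    div( eps(r) grad phi ) = -rho / eps0,

which is discretized on a cubic grid with a 7-point finite-volume
stencil and harmonic-mean dielectric on cell faces.  The dielectric is
``eps_protein`` (default 4) inside any atom's van der Waals sphere and
``eps_solvent`` (default 80, the electrolyte) elsewhere, including the
pore lumen.  Charges are splatted trilinearly onto grid nodes;
Dirichlet boundary values are the summed Coulomb potentials in the
solvent dielectric.  Potentials are reported in mV.

The axial profile phi(x0, y0, z) is parameterized by Fmax, Fmin and
zmin, and compared to a template profile by RMSE and by relative
deviations of the three parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates
from scipy.sparse.linalg import cg

from .structio import Structure

__all__ = [
    "GridConfig",
    "PotentialGrid",
    "AxialProfile",
    "ProfileParams",
    "PointCharge",
    "assign_charges",
    "solve_poisson",
    "axial_profile",
    "profile_params",
    "profile_distance",
    "read_pqr",
]

# e / (4 pi eps0) in mV * Angstrom per elementary charge
_COULOMB_MV_A = 1.602176634e-19 / (4.0 * np.pi * 8.8541878128e-12) * 1e13
# e / eps0 in mV * Angstrom (source strength for the FD solve)
_E_OVER_EPS0_MV_A = _COULOMB_MV_A * 4.0 * np.pi

_VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "SE": 1.9}

#: formal charge scheme: (res_name, atom_name) -> partial charge in e
_FORMAL_SIDECHAIN = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}


@dataclass(frozen=True)
class PointCharge:
    coord: tuple[float, float, float]
    charge: float  # elementary charges
    radius: float = 1.7  # Angstrom, for dielectric painting


@dataclass
class GridConfig:
    """Cubic solver grid (defaults follow the channel-study setup)."""

    dims: tuple[int, int, int] = (129, 129, 129)
    spacing: float = 1.0
    eps_protein: float = 4.0
    eps_solvent: float = 80.0
    boundary: str = "coulomb"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cg_tol: float = 1e-6
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if any(d % 2 == 0 or d < 3 for d in self.dims):
            raise ValueError("grid dims must be odd and >= 3 (center on a node)")
        if self.spacing <= 0 or self.eps_protein <= 0 or self.eps_solvent <= 0:
            raise ValueError("spacing and dielectric constants must be positive")

    @property
    def origin(self) -> np.ndarray:
        c = np.asarray(self.center, float)
        half = (np.asarray(self.dims) - 1) / 2.0 * self.spacing
        return c - half


@dataclass
class PotentialGrid:
    """3D scalar potential in mV on a regular grid."""

    values: np.ndarray
    origin: np.ndarray
    spacing: float

    def sample(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian points, shape (n, 3)."""
        pts = (np.asarray(xyz, float) - self.origin) / self.spacing
        return map_coordinates(self.values, pts.T, order=1, mode="nearest")


@dataclass
class AxialProfile:
    """Potential along a line parallel to z at fixed (x0, y0)."""

    z: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        self.phi = np.asarray(self.phi, float)
        if self.z.shape != self.phi.shape:
            raise ValueError("z and phi must have equal lengths")
        if self.z.size > 1 and not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing")


@dataclass
class ProfileParams:
    fmax: float
    fmin: float
    zmin: float
    tie_flag: bool = False
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Charging
# ---------------------------------------------------------------------------

def assign_charges(structure: Structure, scheme: str = "formal", pqr_path=None) -> list[PointCharge]:
    """Assign point charges to a structure.

    ``formal``: integer side-chain charges split over the terminal
    equivalent atoms (Asp/Glu -1, Lys/Arg +1) plus +1 on each chain
    N-terminal N and -1 on each C-terminal O/OXT.  ``pqr_file``: per-
    atom charges and radii from a PQR file (positions taken from the
    PQR itself).
    """
    if scheme == "pqr_file":
        if pqr_path is None:
            raise ValueError("pqr_file scheme requires pqr_path")
        return read_pqr(pqr_path)
    if scheme != "formal":
        raise ValueError(f"unknown charge scheme {scheme!r}")
    charges: list[PointCharge] = []

    def _add(coord, q, element):
        charges.append(PointCharge(tuple(coord), q, _VDW_RADII.get(element, 1.7)))

    for ch in structure.chains:
        for r in ch.residues:
            for a in r.atoms:
                q = _FORMAL_SIDECHAIN.get((r.res_name, a.name))
                if q is not None:
                    _add(a.coord, q, a.element)
        # termini
        first, last = ch.residues[0], ch.residues[-1]
        if first.has_atom("N"):
            _add(first.atom("N").coord, 1.0, "N")
        term_ox = [a for a in last.atoms if a.name in ("O", "OXT")]
        for a in term_ox:
            _add(a.coord, -1.0 / len(term_ox), "O")
    return charges


def read_pqr(path) -> list[PointCharge]:
    """Read ATOM/HETATM records of a PQR file (whitespace-separated)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            x, y, z, q, r = map(float, parts[-5:])
            out.append(PointCharge((x, y, z), q, r))
    if not out:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return out


# ---------------------------------------------------------------------------
# Poisson solve
# ---------------------------------------------------------------------------

def _dielectric_map(charged_atoms, structure: Optional[Structure], config: GridConfig) -> np.ndarray:
    """Node-centered dielectric: eps_protein inside any vdW sphere."""
    nx, ny, nz = config.dims
    eps = np.full(config.dims, config.eps_solvent)
    origin = config.origin
    h = config.spacing
    spheres = []
    if structure is not None:
        for r in structure.residues():
            for a in r.atoms:
                spheres.append((a.coord, _VDW_RADII.get(a.element.upper(), 1.7)))
    else:
        for c in charged_atoms:
            spheres.append((np.asarray(c.coord), c.radius))
    for center, radius in spheres:
        lo = np.maximum(np.floor((center - radius - origin) / h).astype(int), 0)
        hi = np.minimum(np.ceil((center + radius - origin) / h).astype(int) + 1, config.dims)
        if np.any(lo >= hi):
            continue
        xs = origin[0] + h * np.arange(lo[0], hi[0])
        ys = origin[1] + h * np.arange(lo[1], hi[1])
        zs = origin[2] + h * np.arange(lo[2], hi[2])
        dx2 = (xs - center[0])[:, None, None] ** 2
        dy2 = (ys - center[1])[None, :, None] ** 2
        dz2 = (zs - center[2])[None, None, :] ** 2
        inside = dx2 + dy2 + dz2 <= radius**2
        sub = eps[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = config.eps_protein
    return eps


def _splat_charges(charges, config: GridConfig) -> np.ndarray:
    """Trilinear charge deposition onto grid nodes (units: e)."""
    rho = np.zeros(config.dims)
    origin = config.origin
    h = config.spacing
    for c in charges:
        g = (np.asarray(c.coord, float) - origin) / h
        i0 = np.floor(g).astype(int)
        f = g - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((1 - f[0]) if dx == 0 else f[0]) * \
                        ((1 - f[1]) if dy == 0 else f[1]) * \
                        ((1 - f[2]) if dz == 0 else f[2])
                    idx = i0 + (dx, dy, dz)
                    if np.all(idx >= 0) and np.all(idx < config.dims):
                        rho[tuple(idx)] += w * c.charge
    return rho


def _coulomb_boundary(charges, config: GridConfig) -> np.ndarray:
    """Dirichlet boundary: Coulomb sum in the solvent dielectric (mV)."""
    nx, ny, nz = config.dims
    phi = np.zeros(config.dims)
    origin = config.origin
    h = config.spacing
    # evaluate on the six faces only
    faces = []
    grid = [origin[d] + h * np.arange(config.dims[d]) for d in range(3)]
    mask = np.zeros(config.dims, bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    idx = np.argwhere(mask)
    pts = origin + idx * h
    vals = np.zeros(len(pts))
    for c in charges:
        d = np.linalg.norm(pts - np.asarray(c.coord), axis=1)
        np.maximum(d, 0.5 * h, out=d)
        vals += _COULOMB_MV_A * c.charge / (config.eps_solvent * d)
    phi[mask] = vals
    return phi


def solve_poisson(charges, config: GridConfig, structure: Optional[Structure] = None) -> PotentialGrid:
    """Solve the two-dielectric Poisson equation on the grid.

    ``charges`` is a list of :class:`PointCharge`; when ``structure`` is
    given, its atoms (not just the charged ones) paint the protein
    dielectric region.  Returns the potential in mV.
    """
    if charges:
        coords = np.array([c.coord for c in charges])
        margin_lo = coords.min(0) - config.origin
        margin_hi = config.origin + (np.asarray(config.dims) - 1) * config.spacing - coords.max(0)
        if margin_lo.min() < 10.0 or margin_hi.min() < 10.0:
            warnings.warn("grid margin around charges is below 10 A; boundary artifacts possible", stacklevel=2)
    eps = _dielectric_map(charges, structure, config)
    rho = _splat_charges(charges, config)
    phi_b = _coulomb_boundary(charges, config)
    nx, ny, nz = config.dims
    h = config.spacing

    # harmonic-mean dielectric on faces along each axis
    def hmean(a, b):
        return 2.0 * a * b / (a + b)

    eps_x = hmean(eps[:-1, :, :], eps[1:, :, :])
    eps_y = hmean(eps[:, :-1, :], eps[:, 1:, :])
    eps_z = hmean(eps[:, :, :-1], eps[:, :, 1:])

    interior = np.ones(config.dims, bool)
    interior[0, :, :] = interior[-1, :, :] = False
    interior[:, 0, :] = interior[:, -1, :] = False
    interior[:, :, 0] = interior[:, :, -1] = False
    n_int = int(interior.sum())
    index = -np.ones(config.dims, dtype=np.int64)
    index[interior] = np.arange(n_int)

    ii, jj, kk = np.nonzero(interior)
    rows, cols, data = [], [], []
    b = rho[ii, jj, kk] * _E_OVER_EPS0_MV_A / h  # (q/h^3) * h^2 scaling
    diag = np.zeros(n_int)
    row_ids = index[ii, jj, kk]
    for axis, eps_face in ((0, eps_x), (1, eps_y), (2, eps_z)):
        for sign in (-1, 1):
            off = [0, 0, 0]
            off[axis] = sign
            ni, nj, nk = ii + off[0], jj + off[1], kk + off[2]
            if sign < 0:
                face = eps_face[ni if axis == 0 else ii, nj if axis == 1 else jj, nk if axis == 2 else kk]
            else:
                face = eps_face[ii, jj, kk]
            diag += face
            nbr_interior = interior[ni, nj, nk]
            rows.append(row_ids[nbr_interior])
            cols.append(index[ni[nbr_interior], nj[nbr_interior], nk[nbr_interior]])
            data.append(-face[nbr_interior])
            # Dirichlet neighbours contribute to the RHS
            bmask = ~nbr_interior
            if bmask.any():
                np.add.at(b, np.nonzero(bmask)[0], face[bmask] * phi_b[ni[bmask], nj[bmask], nk[bmask]])

    rows.append(row_ids)
    cols.append(row_ids)
    data.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(n_int, n_int)
    )
    M = sparse.diags(1.0 / A.diagonal())
    x, info = cg(A, b, rtol=config.cg_tol, maxiter=config.max_iter, M=M)
    if info > 0:
        res = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-30)
        raise RuntimeError(f"Poisson solve did not converge in {config.max_iter} iterations (residual {res:.2e})")
    phi = phi_b.copy()
    phi[interior] = x
    return PotentialGrid(values=phi, origin=config.origin, spacing=h)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def axial_profile(grid: PotentialGrid, axis_xy: tuple[float, float] = (0.0, 0.0),
                  z_range: Optional[tuple[float, float]] = None, step: float = 1.0) -> AxialProfile:
    """Sample the potential along (x0, y0, z) by trilinear interpolation."""
    nx, ny, nz = grid.values.shape
    zlo_grid = grid.origin[2]
    zhi_grid = grid.origin[2] + (nz - 1) * grid.spacing
    if z_range is None:
        z_range = (zlo_grid, zhi_grid)
    zlo, zhi = z_range
    x0, y0 = axis_xy
    if not (grid.origin[0] <= x0 <= grid.origin[0] + (nx - 1) * grid.spacing
            and grid.origin[1] <= y0 <= grid.origin[1] + (ny - 1) * grid.spacing
            and zlo_grid <= zlo and zhi <= zhi_grid):
        raise ValueError("axial line outside grid bounds")
    z = np.arange(zlo, zhi + 0.5 * step, step)
    pts = np.column_stack([np.full_like(z, x0), np.full_like(z, y0), z])
    return AxialProfile(z=z, phi=grid.sample(pts))


def profile_params(profile: AxialProfile) -> ProfileParams:
    """Fmax, Fmin and zmin (first occurrence on ties, flagged)."""
    if profile.z.size == 0:
        raise ValueError("empty profile")
    fmax = float(profile.phi.max())
    fmin = float(profile.phi.min())
    imin = int(np.argmin(profile.phi))
    ties = int(np.sum(profile.phi == fmin)) > 1
    return ProfileParams(fmax=fmax, fmin=fmin, zmin=float(profile.z[imin]), tie_flag=ties)


def profile_distance(profile: AxialProfile, template: AxialProfile) -> dict[str, float]:
    """RMSE (mV) on the common z grid plus relative parameter deviations."""
    zlo = max(profile.z.min(), template.z.min())
    zhi = min(profile.z.max(), template.z.max())
    if zhi <= zlo:
        raise ValueError("profiles have no z overlap")
    common = template.z[(template.z >= zlo) & (template.z <= zhi)]
    p = np.interp(common, profile.z, profile.phi)
    t = np.interp(common, template.z, template.phi)
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    pp = profile_params(AxialProfile(common, p))
    tp = profile_params(AxialProfile(common, t))

    def rel(x, x_t):
        return abs(x - x_t) / abs(x_t) if x_t != 0 else np.inf

    return {
        "rmse": rmse,
        "dFmax": rel(pp.fmax, tp.fmax),
        "dFmin": rel(pp.fmin, tp.fmin),
        "dzmin": rel(pp.zmin, tp.zmin),
    }
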