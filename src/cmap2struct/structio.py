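"""Structure data model and PDB input/output.

The in-memory model is a minimal chain/residue/atom hierarchy with
coordinates in Angstrom.  Reading and writing of the fixed-width PDB
format is delegated to :mod:`biotite`; on read, hydrogens, waters, ions
and HETATM records are dropped and alternate locations are resolved to
the highest-occupancy conformer, so "full atom" throughout this package
means *all heavy atoms*.

Concatenated residue indices (position in chain-concatenation order,
1-based, chains in file order) are the coordinate system shared with the
contact-map modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "CaTrace",
    "read_pdb",
    "write_pdb",
    "extract_ca_trace",
]

#: residues treated as solvent/ions and excluded on read
_EXCLUDED_RES = {"HOH", "WAT", "DOD", "K", "NA", "CL", "MG", "CA", "ZN", "SO4", "PO4"}


@dataclass
class Atom:
    """A single heavy atom with coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be 3 finite components")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Atom):
            return NotImplemented
        return self.name == other.name and np.allclose(self.coord, other.coord, atol=5e-4)


@dataclass
class Residue:
    """One amino-acid residue: an ordered collection of heavy atoms."""

    chain_id: str
    seq_index: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain_id}{self.seq_index} ({self.res_name}) has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """Ordered chains of residues; chain order defines concatenation order."""

    chains: list[Chain] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- derived views ---------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        """Residues in concatenated (chain-file) order."""
        for ch in self.chains:
            yield from ch.residues

    @property
    def n_residues(self) -> int:
        return sum(len(ch) for ch in self.chains)

    @property
    def chain_ids(self) -> list[str]:
        return [ch.chain_id for ch in self.chains]

    @property
    def chain_layout(self) -> list[tuple[str, int]]:
        return [(ch.chain_id, len(ch)) for ch in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} (have {self.chain_ids})")

    def sequence(self) -> list[str]:
        return [r.res_name for r in self.residues()]

    def coords(self) -> np.ndarray:
        """All atom coordinates, concatenated order, shape (n_atoms, 3)."""
        return np.array([a.coord for r in self.residues() for a in r.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A copy with every coordinate mapped ``x -> R @ x + t``."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = Structure(metadata=dict(self.metadata))
        for ch in self.chains:
            new_ch = Chain(ch.chain_id)
            for r in ch.residues:
                new_r = Residue(r.chain_id, r.seq_index, r.res_name)
                for a in r.atoms:
                    new_r.atoms.append(
                        Atom(a.name, a.element, rotation @ a.coord + translation, a.occupancy, a.bfactor)
                    )
                new_ch.residues.append(new_r)
            out.chains.append(new_ch)
        return out

    def copy(self) -> "Structure":
        return self.transformed(np.eye(3), np.zeros(3))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        if self.chain_layout != other.chain_layout:
            return False
        for r1, r2 in zip(self.residues(), other.residues()):
            if (r1.seq_index, r1.res_name) != (r2.seq_index, r2.res_name):
                return False
            if r1.atoms != r2.atoms:
                return False
        return True


@dataclass
class CaTrace:
    """Ordered Calpha coordinates with chain-break bookkeeping.

    ``chain_breaks`` holds 0-based point indices ``i`` such that no bond
    constraint links point ``i`` to point ``i + 1`` (i.e. the break falls
    *after* the (i+1)-th point in 1-based counting).
    """

    points: np.ndarray
    chain_breaks: frozenset[int] = frozenset()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("trace coordinates must be finite")
        self.chain_breaks = frozenset(int(i) for i in self.chain_breaks)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Half-open ``(start, stop)`` point ranges of bonded segments."""
        starts = [0] + sorted(i + 1 for i in self.chain_breaks if i + 1 < len(self))
        stops = sorted(i + 1 for i in self.chain_breaks if i + 1 < len(self)) + [len(self)]
        return list(zip(starts, stops))

    def bonded_pairs(self) -> np.ndarray:
        """Indices i of bonded pairs (i, i+1), shape (n_bonds,)."""
        idx = np.arange(len(self) - 1)
        mask = ~np.isin(idx, list(self.chain_breaks))
        return idx[mask]


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def _from_atom_array(arr: bst.AtomArray, source: str) -> Structure:
    struct = Structure(metadata={"source": source})
    current: Optional[Chain] = None
    current_res: Optional[Residue] = None
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        rid = int(arr.res_id[i])
        rname = str(arr.res_name[i])
        if current is None or current.chain_id != cid:
            current = Chain(cid)
            struct.chains.append(current)
            current_res = None
        if current_res is None or current_res.seq_index != rid:
            current_res = Residue(cid, rid, rname)
            current.residues.append(current_res)
        occ = float(arr.occupancy[i]) if "occupancy" in arr.get_annotation_categories() else 1.0
        bf = float(arr.b_factor[i]) if "b_factor" in arr.get_annotation_categories() else 0.0
        current_res.atoms.append(
            Atom(str(arr.atom_name[i]), str(arr.element[i]), np.array(arr.coord[i]), occ, bf)
        )
    return struct


def read_pdb(path, model: int = 1, chains: Optional[Sequence[str]] = None) -> Structure:
    """Read a heavy-atom protein :class:`Structure` from a PDB file.

    Hydrogens, waters, ions and all HETATM records are excluded; altlocs
    resolve to the highest-occupancy conformer.

    Parameters
    ----------
    path:
        PDB file path.
    model:
        1-based model number.
    chains:
        Optional subset of chain ids to keep (file order preserved).
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=model, altloc="occupancy", extra_fields=["occupancy", "b_factor"])
    mask = (
        bst.filter_amino_acids(arr)
        & ~arr.hetero
        & (arr.element != "H")
        & (arr.element != "D")
        & ~np.isin(arr.res_name, list(_EXCLUDED_RES))
    )
    arr = arr[mask]
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no protein ATOM records")
    if chains is not None:
        present = set(np.unique(arr.chain_id).astype(str))
        missing = [c for c in chains if c not in present]
        if missing:
            raise ValueError(f"{path}: requested chain(s) {missing} absent (present: {sorted(present)})")
        arr = arr[np.isin(arr.chain_id, list(chains))]
    struct = _from_atom_array(arr, source=str(path))
    struct.metadata["model"] = model
    return struct


def _to_atom_array(structure: Structure) -> bst.AtomArray:
    n = sum(len(r.atoms) for r in structure.residues())
    arr = bst.AtomArray(n)
    arr.add_annotation("occupancy", float)
    arr.add_annotation("b_factor", float)
    i = 0
    for ch in structure.chains:
        for r in ch.residues:
            for a in r.atoms:
                arr.chain_id[i] = ch.chain_id
                arr.res_id[i] = r.seq_index
                arr.res_name[i] = r.res_name
                arr.atom_name[i] = a.name
                arr.element[i] = a.element
                arr.coord[i] = a.coord
                arr.occupancy[i] = a.occupancy
                arr.b_factor[i] = a.bfactor
                arr.hetero[i] = False
                i += 1
    return arr


def write_pdb(structure: Structure, path) -> None:
    """Write ``structure`` as fixed-width PDB (coordinates to 3 decimals)."""
    if structure.n_residues == 0:
        raise ValueError("cannot write an empty structure")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    pdb.write(str(path))


def extract_ca_trace(structure: Structure) -> CaTrace:
    """Calpha coordinates in concatenated order with chain boundaries.

    Raises if any residue lacks a CA atom, naming the residue.
    """
    points = []
    breaks = set()
    pos = 0
    for ch in structure.chains:
        for r in ch.residues:
            if not r.has_atom("CA"):
                raise ValueError(f"residue {r.chain_id}{r.seq_index} ({r.res_name}) lacks a CA atom")
            points.append(r.atom("CA").coord)
            pos += 1
        breaks.add(pos - 1)
    breaks.discard(pos - 1)  # no break after the final chain
    missing_backbone = [
        f"{r.chain_id}{r.seq_index}"
        for r in structure.residues()
        if not all(r.has_atom(a) for a in ("N", "C"))
    ]
    if missing_backbone:
        warnings.warn(f"{len(missing_backbone)} residue(s) missing backbone atoms besides CA", stacklevel=2)
    return CaTrace(
        points=np.array(points),
        chain_breaks=frozenset(breaks),
        provenance={"source": structure.metadata.get("source", "memory"), "chain_ids": structure.chain_ids},
    )
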