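"""Structures, trajectories and plain-text tables.

Multi-model PDB ensembles are read and written through :mod:`biotite`;
COLVAR/HILLS-style whitespace tables use a ``#!``-prefixed header line so
standard plotting tools can skip it.  All coordinates are nm internally;
the Å↔nm conversion happens only here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import ANGSTROM_PER_NM, residue_mass


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, 1-based PDB residue numbering, coordinates in nm."""

    atom_name: str
    residue_index: int
    residue_name: str
    coordinates: tuple[float, float, float]
    mass: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("atom coordinates must be finite")
        if self.mass <= 0:
            raise ValueError("atom mass must be positive")
        if self.residue_index < 1:
            raise ValueError("residue_index is 1-based and must be >= 1")


class Structure:
    """An ordered set of atoms belonging to one model of an ensemble.

    Parameters
    ----------
    atoms : sequence of AtomRecord
        At least one atom; residue indices non-decreasing.
    model_id : int
        Model number within a multi-model ensemble (1-based).
    """

    def __init__(self, atoms: Sequence[AtomRecord], model_id: int = 1):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a Structure needs at least one atom")
        idx = [a.residue_index for a in atoms]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be non-decreasing")
        self.atoms = atoms
        self.model_id = int(model_id)
        self._coords = np.array([a.coordinates for a in atoms], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        coords_nm: np.ndarray,
        residue_indices: Iterable[int],
        residue_names: Iterable[str] | str = "ALA",
        atom_names: Iterable[str] | str = "CA",
        masses: Iterable[float] | float | None = None,
        model_id: int = 1,
    ) -> "Structure":
        coords_nm = np.asarray(coords_nm, dtype=float)
        n = coords_nm.shape[0]
        res_idx = list(residue_indices)
        res_names = [residue_names] * n if isinstance(residue_names, str) else list(residue_names)
        at_names = [atom_names] * n if isinstance(atom_names, str) else list(atom_names)
        if masses is None:
            mass_list = [residue_mass(r) for r in res_names]
        elif np.isscalar(masses):
            mass_list = [float(masses)] * n
        else:
            mass_list = [float(m) for m in masses]
        atoms = [
            AtomRecord(at_names[i], int(res_idx[i]), res_names[i],
                       tuple(coords_nm[i]), mass_list[i])
            for i in range(n)
        ]
        return cls(atoms, model_id=model_id)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinates in nm (copy-safe view)."""
        return self._coords

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    @property
    def atom_names(self) -> list[str]:
        return [a.atom_name for a in self.atoms]

    @property
    def residue_names(self) -> list[str]:
        return [a.residue_name for a in self.atoms]

    def __len__(self) -> int:
        return len(self.atoms)

    def with_coords(self, coords_nm: np.ndarray, model_id: int | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        return Structure.from_arrays(
            coords_nm,
            self.residue_indices,
            self.residue_names,
            self.atom_names,
            self.masses,
            model_id=self.model_id if model_id is None else model_id,
        )


@dataclass
class ResidueSelection:
    """Ordered set of 1-based residue indices."""

    residue_indices: tuple[int, ...]

    def __init__(self, residue_indices: Iterable[int]):
        seen: dict[int, None] = {}
        for i in residue_indices:
            seen.setdefault(int(i), None)
        object.__setattr__(self, "residue_indices", tuple(seen))

    @classmethod
    def from_range(cls, start: int, stop: int) -> "ResidueSelection":
        """Inclusive residue range, e.g. ``from_range(1, 171)``."""
        return cls(range(start, stop + 1))

    @classmethod
    def parse(cls, text: str) -> "ResidueSelection":
        """Parse ``"1:171"`` or ``"32-35,45-48"`` style selections."""
        indices: list[int] = []
        for chunk in text.replace(":", "-").split(","):
            chunk = chunk.strip()
            if "-" in chunk:
                lo, hi = chunk.split("-")
                indices.extend(range(int(lo), int(hi) + 1))
            elif chunk:
                indices.append(int(chunk))
        return cls(indices)

    def __len__(self) -> int:
        return len(self.residue_indices)

    def __iter__(self):
        return iter(self.residue_indices)


class Trajectory:
    """Coordinate frames over time on a fixed topology.

    frames: (n_frames, n_atoms, 3) nm; times: ps, strictly increasing.
    """

    def __init__(self, topology: Structure, frames: np.ndarray, times: np.ndarray):
        frames = np.asarray(frames, dtype=float)
        times = np.asarray(times, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[1] != len(topology):
            raise ValueError("frame atom count does not match topology")
        if frames.shape[0] != times.shape[0]:
            raise ValueError("times length does not match frame count")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def with_frames(self, frames: np.ndarray) -> "Trajectory":
        return Trajectory(self.topology, frames, self.times)

    def slice_frames(self, idx) -> "Trajectory":
        return Trajectory(self.topology, self.frames[idx], self.times[idx])


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: Path) -> int:
    """Pre-scan ATOM records; return their count, raising with line numbers."""
    n_atom_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n_atom_lines += 1
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"{path}: malformed ATOM record at line {lineno}: too short")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise PDBParseError(
                        f"{path}: malformed ATOM record at line {lineno}: {exc}"
                    ) from exc
    return n_atom_lines


def read_pdb_models(path: str | Path) -> list[Structure]:
    """Read a (multi-model) PDB file into one :class:`Structure` per MODEL.

    Coordinates are converted Å→nm.  A file without MODEL records yields a
    single Structure.  Missing masses default to per-residue proxy masses.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _validate_pdb_lines(path) == 0:
        raise PDBParseError(f"{path}: no ATOM records found")

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack, coords in Å
    structures = []
    for m in range(stack.stack_depth()):
        arr = stack[m]
        coords_nm = np.asarray(arr.coord, dtype=float) / ANGSTROM_PER_NM
        structures.append(
            Structure.from_arrays(
                coords_nm,
                arr.res_id,
                list(arr.res_name),
                list(arr.atom_name),
                model_id=m + 1,
            )
        )
    return structures


def write_pdb_models(path: str | Path, structures: Sequence[Structure] | Trajectory) -> None:
    """Write structures (or a trajectory's frames) as a multi-model PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(structures, Trajectory):
        topo = structures.topology
        models = [topo.with_coords(f, model_id=i + 1)
                  for i, f in enumerate(structures.frames)]
    else:
        models = list(structures)
    if not models:
        raise ValueError("nothing to write")

    ref = models[0]
    n = len(ref)
    arrays = []
    for s in models:
        arr = struc.AtomArray(n)
        arr.coord = s.coords * ANGSTROM_PER_NM
        arr.res_id = s.residue_indices
        arr.res_name = np.array(s.residue_names)
        arr.atom_name = np.array(s.atom_names)
        arr.element = np.array(["C"] * n)
        arr.chain_id = np.array(["A"] * n)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def select_residues(
    structure: Structure,
    selection: ResidueSelection,
    atom_name: str | None = None,
) -> np.ndarray:
    """Ordered atom indices of ``structure`` restricted to ``selection``.

    Raises if any requested residue (optionally with the given atom name)
    is absent, listing the missing indices.
    """
    if len(selection) == 0:
        raise ValueError("empty residue selection")
    res_idx = structure.residue_indices
    names = np.array(structure.atom_names)
    wanted = set(selection.residue_indices)
    mask = np.isin(res_idx, list(wanted))
    if atom_name is not None:
        mask &= names == atom_name
    present = set(res_idx[mask].tolist())
    missing = sorted(wanted - present)
    if missing:
        raise ValueError(f"residues not found in structure: {missing}")
    return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# COLVAR / HILLS style tables
# ---------------------------------------------------------------------------

def write_table(path: str | Path, column_names: Sequence[str], rows: np.ndarray) -> None:
    """Write a whitespace table with a ``#! FIELDS ...`` header line."""
    rows = np.asarray(rows, dtype=float)
    if rows.size == 0:
        rows = rows.reshape(0, len(column_names))
    if rows.ndim != 2 or rows.shape[1] != len(column_names):
        raise ValueError("rows must be rectangular with one column per name")
    header = "#! FIELDS " + " ".join(column_names)
    np.savetxt(path, rows, header=header, comments="", fmt="%.17g")


def read_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a table written by :func:`write_table`; returns (names, rows)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#!"):
        raise ValueError(f"{path}: missing '#!' header line")
    names = first.split()[2:]
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message=".*no data.*")
        rows = np.loadtxt(path, comments="#", ndmin=2)
    if rows.size == 0:
        rows = np.empty((0, len(names)))
    return names, rows
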