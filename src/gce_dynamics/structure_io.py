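"""Homodimer structures, trajectories and residue-level atom selections.

Structures are plain containers of atom records with author (bovine)
residue numbering; trajectories pair one topology with a stack of
coordinate frames in Angstrom.  PDB parsing and writing is delegated to
biotite; the simple XYZ block format is handled directly.

Dialect choices for PDB files: the first alternate location is kept,
HETATM records are ignored, occupancy/B-factor are written as 1.00/0.00,
and coordinates are rendered with three decimals in the fixed-width
field (values outside +-9999.999 A are rejected rather than truncated).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io

from gce_dynamics.errors import (
    EmptyInputError,
    ParseError,
    SelectionError,
    StructuralMismatchError,
)

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "select_backbone_carbon",
]

#: Largest coordinate magnitude representable in the fixed-width "%8.3f"
#: PDB coordinate field.
_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


@dataclass(frozen=True)
class AtomRecord:
    """One atom: chain, author residue number, residue/atom names, position (A)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite position for atom {self.label}")
        object.__setattr__(self, "position", pos)

    @property
    def label(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)


@dataclass
class Structure:
    """Ordered collection of atoms; dimer analyses expect exactly two chains."""

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyInputError("structure contains no atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.chain_id, None)
        return list(seen)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in A."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with every atom moved to ``coords``."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructuralMismatchError(
                f"expected coordinates of shape {(self.n_atoms, 3)}, got {coords.shape}"
            )
        atoms = [
            AtomRecord(a.chain_id, a.residue_number, a.residue_name, a.atom_name, xyz)
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms)

    def residues(self) -> list[tuple[str, int, str]]:
        """(chain, residue_number, residue_name) in order of first appearance."""
        seen: dict[tuple[str, int], str] = {}
        for atom in self.atoms:
            seen.setdefault((atom.chain_id, atom.residue_number), atom.residue_name)
        return [(c, r, name) for (c, r), name in seen.items()]


@dataclass
class Trajectory:
    """Fixed topology plus an ordered stack of coordinate frames (A)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise StructuralMismatchError(
                f"frames must have shape (n_frames, n_atoms, 3), got {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise EmptyInputError("trajectory must contain at least one frame")
        if frames.shape[1] != self.topology.n_atoms:
            raise StructuralMismatchError(
                f"frames carry {frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        self.frames = frames

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    def frame(self, index: int) -> Structure:
        return self.topology.with_coords(self.frames[index])

    def with_frames(self, frames: np.ndarray) -> "Trajectory":
        return Trajectory(self.topology, frames)


@dataclass
class Selection:
    """Ordered atom indices into a structure, with parallel residue labels."""

    atom_indices: list[int]
    labels: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        if len(self.atom_indices) != len(self.labels):
            raise ValueError("atom_indices and labels must be parallel")
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.atom_indices)

    def coords(self, frame: np.ndarray) -> np.ndarray:
        """Coordinates of the selected atoms within one frame array."""
        return np.asarray(frame, dtype=float)[self.atom_indices]


# ---------------------------------------------------------------------------
# biotite conversion helpers


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _to_atom_array(structure: Structure) -> struc.AtomArray:
    n = structure.n_atoms
    array = struc.AtomArray(n)
    array.chain_id = np.array([a.chain_id for a in structure.atoms], dtype="U4")
    array.res_id = np.array([a.residue_number for a in structure.atoms], dtype=int)
    array.res_name = np.array([a.residue_name for a in structure.atoms], dtype="U5")
    array.atom_name = np.array([a.atom_name for a in structure.atoms], dtype="U6")
    array.element = np.array(
        [_element_of(a.atom_name) for a in structure.atoms], dtype="U2"
    )
    array.hetero = np.zeros(n, dtype=bool)
    array.coord = structure.coords.astype(np.float32)
    return array


def _from_atom_array(array: struc.AtomArray) -> Structure:
    keep = ~array.hetero
    array = array[keep]
    if array.array_length() == 0:
        raise EmptyInputError("no ATOM records found")
    atoms = [
        AtomRecord(
            chain_id=str(array.chain_id[i]),
            residue_number=int(array.res_id[i]),
            residue_name=str(array.res_name[i]),
            atom_name=str(array.atom_name[i]),
            position=np.asarray(array.coord[i], dtype=float),
        )
        for i in range(array.array_length())
    ]
    return Structure(atoms)


def _validate_pdb_lines(path: Path) -> None:
    """Fail early with the offending line number on malformed ATOM records."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}: truncated ATOM record at line {lineno}")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed ATOM record at line {lineno}: {exc}"
                ) from exc


# ---------------------------------------------------------------------------
# operations


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a single-model structure file.

    Atom order, chain identifiers and author residue numbers are preserved
    verbatim; coordinates are in Angstrom.  Only the first alternate
    location of each atom is kept and HETATM records are dropped.
    """
    path = Path(path)
    if format != "pdb":
        raise ValueError(f"unsupported structure format: {format!r}")
    _validate_pdb_lines(path)
    try:
        pdb_file = pdb_io.PDBFile.read(str(path))
        array = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises various InvalidFileError types
        if isinstance(exc, (EmptyInputError, ParseError)):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    return _from_atom_array(array)


def read_trajectory(
    path: str | Path,
    format: str = "pdb",
    topology: Structure | None = None,
) -> Trajectory:
    """Read a multi-model PDB or XYZ block file as a trajectory.

    One frame is produced per MODEL (PDB) or per block (XYZ).  When no
    topology is given it is taken from the first model; for XYZ input
    without a topology a placeholder topology (single chain, one residue
    per atom) is synthesised, since the format carries no residue
    information.
    """
    path = Path(path)
    if format == "pdb":
        return _read_pdb_trajectory(path, topology)
    if format == "xyz":
        return _read_xyz_trajectory(path, topology)
    raise ValueError(f"unsupported trajectory format: {format!r}")


def _read_pdb_trajectory(path: Path, topology: Structure | None) -> Trajectory:
    _validate_pdb_lines(path)
    try:
        pdb_file = pdb_io.PDBFile.read(str(path))
        stack = pdb_file.get_structure(altloc="first")
    except Exception as exc:
        if isinstance(exc, (EmptyInputError, ParseError)):
            raise
        # biotite reports inconsistent per-model atom counts at this point
        raise StructuralMismatchError(f"{path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    keep = ~stack.hetero
    stack = stack[:, keep]
    if stack.array_length() == 0:
        raise EmptyInputError(f"{path}: no ATOM records found")
    first = _from_atom_array(stack[0])
    topo = topology if topology is not None else first
    frames = np.asarray(stack.coord, dtype=float)
    if frames.shape[1] != topo.n_atoms:
        raise StructuralMismatchError(
            f"{path}: models carry {frames.shape[1]} atoms but topology has "
            f"{topo.n_atoms}"
        )
    return Trajectory(topo, frames)


def _read_xyz_trajectory(path: Path, topology: Structure | None) -> Trajectory:
    blocks: list[np.ndarray] = []
    names: list[str] = []
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: expected atom count at line {i + 1}") from exc
        if len(lines) < i + 2 + n:
            raise ParseError(f"{path}: truncated XYZ block starting at line {i + 1}")
        block = np.empty((n, 3), dtype=float)
        block_names: list[str] = []
        for j in range(n):
            fields = lines[i + 2 + j].split()
            if len(fields) < 4:
                raise ParseError(f"{path}: malformed XYZ atom line {i + 3 + j}")
            block_names.append(fields[0])
            block[j] = [float(fields[1]), float(fields[2]), float(fields[3])]
        if blocks and block.shape[0] != blocks[0].shape[0]:
            raise StructuralMismatchError(
                f"{path}: XYZ block {len(blocks) + 1} has {block.shape[0]} atoms, "
                f"expected {blocks[0].shape[0]}"
            )
        if not blocks:
            names = block_names
        blocks.append(block)
        i += 2 + n
    if not blocks:
        raise EmptyInputError(f"{path}: no XYZ blocks found")
    frames = np.stack(blocks)
    if topology is None:
        atoms = [
            AtomRecord("A", j + 1, "UNK", names[j], frames[0, j])
            for j in range(frames.shape[1])
        ]
        topology = Structure(atoms)
    elif topology.n_atoms != frames.shape[1]:
        raise StructuralMismatchError(
            f"{path}: XYZ blocks carry {frames.shape[1]} atoms but topology has "
            f"{topology.n_atoms}"
        )
    return Trajectory(topology, frames)


def write_trajectory(
    traj: Trajectory, path: str | Path, format: str = "pdb"
) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame) or XYZ.

    PDB coordinates are rendered with three decimals; a coordinate that
    does not fit the fixed-width field raises ``ValueError`` instead of
    being silently truncated.
    """
    path = Path(path)
    if format == "pdb":
        _check_pdb_range(traj.frames)
        array = _to_atom_array(traj.topology)
        stack = struc.stack([array] * traj.frame_count)
        stack.coord = traj.frames.astype(np.float32)
        pdb_file = pdb_io.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))
    elif format == "xyz":
        with open(path, "w") as handle:
            for k in range(traj.frame_count):
                handle.write(f"{traj.topology.n_atoms}\n")
                handle.write(f"frame {k}\n")
                for atom, xyz in zip(traj.topology.atoms, traj.frames[k]):
                    handle.write(
                        f"{_element_of(atom.atom_name)} "
                        f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n"
                    )
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")


def _check_pdb_range(frames: np.ndarray) -> None:
    lo, hi = float(frames.min()), float(frames.max())
    if lo < _PDB_COORD_MIN or hi > _PDB_COORD_MAX:
        raise ValueError(
            f"coordinate range [{lo:.3f}, {hi:.3f}] A does not fit the "
            f"fixed-width PDB field [{_PDB_COORD_MIN}, {_PDB_COORD_MAX}]"
        )


def select_backbone_carbon(
    structure: Structure,
    residues: Sequence[tuple[str, int]],
    atom_name: str = "CA",
) -> Selection:
    """Resolve residues to their representative backbone carbon.

    The representative atom defaults to the alpha-carbon CA — the first
    carbon along the backbone in N->CA->C order — and can be switched to
    the carbonyl C via ``atom_name``.  Exactly one atom is returned per
    requested residue, in request order, regardless of atom ordering
    inside the residue.
    """
    index: dict[tuple[str, int], tuple[int, str]] = {}
    residue_names: dict[tuple[str, int], str] = {}
    for i, atom in enumerate(structure.atoms):
        key = (atom.chain_id, atom.residue_number)
        residue_names.setdefault(key, atom.residue_name)
        if atom.atom_name == atom_name and key not in index:
            index[key] = (i, atom.residue_name)
    indices: list[int] = []
    labels: list[tuple[str, int, str]] = []
    for chain, resnum in residues:
        key = (chain, int(resnum))
        if key not in residue_names:
            raise SelectionError(
                f"residue {resnum} not found in chain {chain!r}"
            )
        if key not in index:
            raise SelectionError(
                f"residue {resnum} in chain {chain!r} has no {atom_name} atom"
            )
        i, res_name = index[key]
        indices.append(i)
        labels.append((chain, int(resnum), res_name))
    return Selection(indices, labels)
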