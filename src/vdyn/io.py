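"""Structure and trajectory I/O plus atom selections.

Structures are read from PDB files with Biopython; binary trajectory formats
(DCD/XTC/NetCDF) are read through mdtraj, while multi-model PDB files — the
format used by the synthetic generators — are parsed directly.  All
coordinates are held in Angstrom.

Residue numbering follows the PDB sequence numbering and is never rewritten;
selections can carry an explicit offset relating a 0-based array index to the
sequence position so that downstream reports print sequence positions.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_FRAME_INTERVAL_NS

__all__ = [
    "StructureModel",
    "TrajectoryEnsemble",
    "AtomSelection",
    "PDBParseError",
    "SelectionError",
    "load_structure",
    "load_trajectory",
    "select_atoms",
    "write_structure",
    "write_trajectory",
    "write_matrix_csv",
    "read_matrix_csv",
]

_BACKBONE_NAMES = ("N", "CA", "C", "O")
_HYDROGEN_ELEMENTS = ("H", "D")


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a structure."""


class SelectionError(ValueError):
    """Raised when a selection expression is invalid or selects no atoms."""


@dataclasses.dataclass
class StructureModel:
    """A flat atom-record view of one model of a structure.

    Coordinates are in Angstrom.  ``hetero`` flags atoms from HETATM groups
    (heme, ligands, waters); ``resid`` keeps the file's sequence numbering.
    """

    serial: np.ndarray
    name: np.ndarray
    resname: np.ndarray
    resid: np.ndarray
    chain: np.ndarray
    element: np.ndarray
    xyz: np.ndarray
    hetero: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("structure coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    def is_hydrogen(self) -> np.ndarray:
        return np.isin(np.char.upper(self.element.astype(str)), _HYDROGEN_ELEMENTS)

    def hetero_resnames(self) -> list[str]:
        """Distinct residue names of the flagged hetero groups."""
        return sorted(set(self.resname[self.hetero].tolist()))


@dataclasses.dataclass
class TrajectoryEnsemble:
    """An ordered ensemble of coordinate frames over a fixed atom set.

    ``equilibration_start`` is the index of the first frame retained by
    equilibrated-phase analyses (PCA, DCCM, RMSF, FEL); deviation series are
    computed over all frames unless sliced explicitly.
    """

    xyz: np.ndarray
    times: np.ndarray
    topology: StructureModel
    equilibration_start: int = 0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        if self.xyz.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"trajectory has {self.xyz.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.times.shape != (self.xyz.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not 0 <= self.equilibration_start < self.n_frames:
            raise ValueError("equilibration_start must be a valid frame index")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    @property
    def retained_xyz(self) -> np.ndarray:
        """Frames of the equilibrated phase."""
        return self.xyz[self.equilibration_start:]

    @property
    def retained_times(self) -> np.ndarray:
        return self.times[self.equilibration_start:]

    def discard_before(self, time_ns: float) -> "TrajectoryEnsemble":
        """Return a copy with the equilibration cutoff set at ``time_ns``."""
        idx = int(np.searchsorted(self.times, time_ns, side="left"))
        if idx >= self.n_frames:
            raise ValueError(
                f"cutoff {time_ns} ns discards all {self.n_frames} frames"
            )
        return dataclasses.replace(self, equilibration_start=idx)


@dataclasses.dataclass(frozen=True)
class AtomSelection:
    """An ordered, validated set of atom indices into a topology.

    ``indices`` are 0-based positions into the atom array; ``resids`` carry
    the matching sequence positions so reports never print array indices.
    ``offset`` records the array-index-to-sequence-position shift used when a
    downstream consumer works with 0-based positions.
    """

    indices: np.ndarray
    expression: str
    resids: np.ndarray
    exclude: tuple[tuple[int, int], ...] = ()
    offset: int = 0

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size == 0:
            raise SelectionError(f"selection {self.expression!r} is empty")
        if idx.size != np.unique(idx).size or np.any(np.diff(idx) < 0):
            raise ValueError("selection indices must be unique and sorted")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "resids", np.asarray(self.resids, dtype=int))

    def __len__(self) -> int:
        return int(self.indices.size)


def _resolve_altlocs(residue) -> list:
    """Flatten a Biopython residue, keeping the highest-occupancy altloc.

    Ties keep the conformer appearing first in the file.
    """
    atoms = []
    for atom in residue.get_list():
        if atom.is_disordered():
            children = atom.disordered_get_list()
            best = max(
                enumerate(children),
                key=lambda pair: (pair[1].get_occupancy() or 0.0, -pair[0]),
            )[1]
            atoms.append(best)
        else:
            atoms.append(atom)
    return atoms


def _model_to_structure(model) -> StructureModel:
    serial, name, resname, resid, chain, element, xyz, hetero = (
        [], [], [], [], [], [], [], []
    )
    for ch in model:
        for residue in ch:
            hetfield = residue.get_id()[0]
            is_het = hetfield.strip() != ""
            for atom in _resolve_altlocs(residue):
                serial.append(atom.get_serial_number() or 0)
                name.append(atom.get_name())
                resname.append(residue.get_resname().strip())
                resid.append(residue.get_id()[1])
                chain.append(ch.get_id())
                element.append((atom.element or "").strip() or "X")
                xyz.append(atom.get_coord())
                hetero.append(is_het)
    if not serial:
        raise PDBParseError("model contains no atoms")
    return StructureModel(
        serial=np.array(serial, dtype=int),
        name=np.array(name),
        resname=np.array(resname),
        resid=np.array(resid, dtype=int),
        chain=np.array(chain),
        element=np.array(element),
        xyz=np.array(xyz, dtype=float),
        hetero=np.array(hetero, dtype=bool),
    )


def _parse_pdb(path: str | os.PathLike):
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("structure", str(path))
    except PDBConstructionException as exc:  # strict mode names the line
        raise PDBParseError(f"malformed PDB record in {path}: {exc}") from exc
    except ValueError as exc:  # e.g. empty file
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    models = list(structure)
    if not models or all(len(list(m.get_atoms())) == 0 for m in models):
        raise PDBParseError(f"no atoms found in {path}")
    return models


def load_structure(path: str | os.PathLike, model: int = 0) -> StructureModel:
    """Read one model of a PDB file into a :class:`StructureModel`.

    Hetero residues (HETATM records, e.g. the heme group ``HEM`` or a bound
    ligand) are retained and flagged.  Alternate locations keep the
    highest-occupancy conformer.
    """
    models = _parse_pdb(path)
    try:
        selected = models[model]
    except IndexError:
        raise PDBParseError(
            f"{path} has {len(models)} model(s); model {model} not present"
        ) from None
    return _model_to_structure(selected)


def load_trajectory(
    path: str | os.PathLike,
    topology: StructureModel,
    frame_interval_ns: float = DEFAULT_FRAME_INTERVAL_NS,
) -> TrajectoryEnsemble:
    """Read a trajectory against a topology.

    Multi-model PDB files are parsed directly; any other extension is handed
    to mdtraj (DCD, XTC, NetCDF, ...).  Frame times are taken from the file
    where available, otherwise computed from ``frame_interval_ns``.
    """
    path = str(path)
    if path.lower().endswith((".pdb", ".ent")):
        frames = [_model_to_structure(m) for m in _parse_pdb(path)]
        counts = {f.n_atoms for f in frames}
        if counts != {topology.n_atoms}:
            raise ValueError(
                f"trajectory frames have {sorted(counts)} atoms but topology "
                f"has {topology.n_atoms}"
            )
        xyz = np.stack([f.xyz for f in frames])
        times = np.arange(len(frames)) * frame_interval_ns
    else:
        import mdtraj as md

        traj = md.load(path, top=_to_mdtraj_topology(topology))
        if traj.n_atoms != topology.n_atoms:
            raise ValueError(
                f"trajectory has {traj.n_atoms} atoms but topology has "
                f"{topology.n_atoms}"
            )
        xyz = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Angstrom
        if traj.time is not None and np.all(np.diff(traj.time) > 0):
            times = np.asarray(traj.time, dtype=float) / 1000.0  # ps -> ns
        else:
            times = np.arange(traj.n_frames) * frame_interval_ns
    return TrajectoryEnsemble(xyz=xyz, times=times, topology=topology)


def _to_mdtraj_topology(structure: StructureModel):
    import mdtraj as md

    top = md.Topology()
    chains: dict[str, object] = {}
    current_key = None
    residue = None
    for i in range(structure.n_atoms):
        cid = str(structure.chain[i])
        if cid not in chains:
            chains[cid] = top.add_chain()
        key = (cid, int(structure.resid[i]), str(structure.resname[i]))
        if key != current_key:
            residue = top.add_residue(
                str(structure.resname[i]), chains[cid], resSeq=int(structure.resid[i])
            )
            current_key = key
        symbol = str(structure.element[i]).capitalize()
        try:
            elem = md.element.get_by_symbol(symbol)
        except KeyError:
            elem = md.element.virtual
        top.add_atom(str(structure.name[i]), elem, residue)
    return top


def write_structure(structure: StructureModel, path: str | os.PathLike) -> None:
    """Write a structure as a single-model PDB file."""
    import mdtraj as md

    traj = md.Trajectory(
        xyz=structure.xyz[np.newaxis] / 10.0, topology=_to_mdtraj_topology(structure)
    )
    traj.save_pdb(str(path))


def write_trajectory(traj: TrajectoryEnsemble, path: str | os.PathLike) -> None:
    """Write a trajectory; multi-model PDB or any mdtraj-supported format."""
    import mdtraj as md

    mtraj = md.Trajectory(
        xyz=traj.xyz / 10.0,
        topology=_to_mdtraj_topology(traj.topology),
        time=traj.times * 1000.0,
    )
    mtraj.save(str(path))


def _parse_ranges(exclude: Iterable) -> tuple[tuple[int, int], ...]:
    ranges = []
    for item in exclude or ():
        if isinstance(item, str):
            lo, _, hi = item.partition("-")
            item = (int(lo), int(hi or lo))
        lo, hi = int(item[0]), int(item[1])
        if hi < lo:
            raise ValueError(f"exclusion range {item} has end before start")
        ranges.append((lo, hi))
    return tuple(ranges)


def select_atoms(
    structure: StructureModel,
    expression: str,
    exclude: Iterable = (),
    offset: int = 0,
) -> AtomSelection:
    """Build an :class:`AtomSelection` from a named atom class.

    Supported expressions: ``"ca"`` (alpha carbons), ``"backbone"``
    (N/CA/C/O), ``"heavy"`` (non-hydrogen protein atoms), ``"all"``, and
    ``"resid LO-HI"`` (all atoms in an inclusive sequence-number range).
    ``exclude`` lists inclusive residue ranges in sequence numbering —
    e.g. the flexible loops 260-270 and 280-288 of CYP3A5 — whose atoms are
    dropped.  A selection that comes out empty raises
    :class:`SelectionError`; silently empty selections are forbidden.
    """
    expr = expression.strip().lower()
    names = np.char.upper(structure.name.astype(str))
    not_h = ~structure.is_hydrogen()
    protein = ~structure.hetero
    if expr in ("ca", "calpha", "c-alpha", "cα"):
        mask = (names == "CA") & protein
    elif expr == "backbone":
        mask = np.isin(names, _BACKBONE_NAMES) & protein & not_h
    elif expr == "heavy":
        mask = protein & not_h
    elif expr == "all":
        mask = np.ones(structure.n_atoms, dtype=bool)
    elif expr.startswith("resid"):
        ((lo, hi),) = _parse_ranges([expr.removeprefix("resid").strip()])
        mask = (structure.resid >= lo) & (structure.resid <= hi)
    else:
        raise SelectionError(f"unsupported selection expression {expression!r}")

    ranges = _parse_ranges(exclude)
    for lo, hi in ranges:
        mask &= ~((structure.resid >= lo) & (structure.resid <= hi))

    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise SelectionError(
            f"selection {expression!r} with exclusions {ranges} selects no atoms"
        )
    return AtomSelection(
        indices=indices,
        expression=expression,
        resids=structure.resid[indices],
        exclude=ranges,
        offset=offset,
    )


def write_matrix_csv(
    matrix: np.ndarray, labels: Sequence[int], path: str | os.PathLike
) -> None:
    """Write a square matrix as CSV with residue-number header and index."""
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(path)


def read_matrix_csv(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a matrix written by :func:`write_matrix_csv`; returns (matrix, labels)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), df.index.to_numpy(dtype=int)
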