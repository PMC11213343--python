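"""Structures, trajectories and atom selections.

Structures are parsed from PDB text (ATOM/MODEL/ENDMDL records) via
Biopython and held as flat numpy-backed containers; trajectories are
ordered coordinate stacks on a fixed topology. Residue indices are
1-based throughout. Binary trajectory formats can be plugged in through
:func:`register_trajectory_adapter` without adding core dependencies.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO

__all__ = [
    "Structure",
    "Trajectory",
    "AtomSelection",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "register_trajectory_adapter",
]


@dataclass
class Structure:
    """A single conformation on a fixed topology.

    Atom order follows the source file; ``residue_ids`` are 1-based and
    non-decreasing along the atom order.
    """

    residue_ids: np.ndarray  # (n_atoms,) int, 1-based
    residue_names: List[str]  # 3-letter codes, per atom
    atom_names: List[str]
    elements: List[str]
    coords: np.ndarray  # (n_atoms, 3) float, Å
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.residue_ids) != len(self.coords):
            raise ValueError("residue_ids and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(np.diff(self.residue_ids) < 0):
            raise ValueError("residue indices must be non-decreasing in atom order")

    @property
    def n_atoms(self) -> int:
        return len(self.residue_ids)

    @property
    def residue_index_list(self) -> np.ndarray:
        """Unique residue ids in order of first appearance."""
        _, first = np.unique(self.residue_ids, return_index=True)
        return self.residue_ids[np.sort(first)]

    @property
    def n_residues(self) -> int:
        return len(self.residue_index_list)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            residue_ids=self.residue_ids,
            residue_names=self.residue_names,
            atom_names=self.atom_names,
            elements=self.elements,
            coords=np.asarray(coords, dtype=float),
            chain_id=self.chain_id,
        )

    def ca_coords(self) -> Tuple[np.ndarray, np.ndarray]:
        """(residue_ids, coords) of Cα atoms in residue order."""
        sel = select_atoms(self, "calpha")
        return self.residue_ids[sel.indices], self.coords[sel.indices]

    def sequence(self) -> str:
        """One-letter sequence over residues (unknown codes become X)."""
        _, first = np.unique(self.residue_ids, return_index=True)
        return "".join(
            _THREE_TO_ONE.get(self.residue_names[k].upper(), "X")
            for k in np.sort(first)
        )


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass
class Trajectory:
    """Ordered frames of coordinates on a fixed topology.

    ``frame_times`` are in ns and strictly increasing; they default to
    the frame index when no sampling interval is known.
    """

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray  # (n_frames,) ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] == 0:
            raise ValueError("trajectory has zero frames")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if len(self.frame_times) != len(self.frames):
            raise ValueError("frame_times length must equal frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def structure_at(self, frame: int) -> Structure:
        return self.topology.with_coords(self.frames[frame])

    def tail_window(self, window_ns: Optional[float]) -> np.ndarray:
        """Frame indices of the trailing window of ``window_ns`` ns.

        ``None`` selects all frames. Raises if the trajectory spans less
        than the requested window.
        """
        if window_ns is None:
            return np.arange(self.n_frames)
        span = self.frame_times[-1] - self.frame_times[0]
        if span < window_ns:
            raise ValueError(
                f"trajectory spans {span} ns, shorter than window {window_ns} ns"
            )
        t0 = self.frame_times[-1] - window_ns
        return np.nonzero(self.frame_times >= t0 - 1e-9)[0]


@dataclass
class AtomSelection:
    """Unique, in-range atom indices into a Structure."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# PDB reading / writing


def _structure_from_model(model, chain_id: Optional[str]) -> Structure:
    rids, rnames, anames, elems, xyz = [], [], [], [], []
    chosen_chain = chain_id
    for chain in model:
        if chosen_chain is None:
            chosen_chain = chain.id
        if chain.id != chosen_chain:
            continue
        for residue in chain:
            het, resseq, _ = residue.id
            if het.strip():  # skip waters / heteroatoms
                continue
            for atom in residue:
                rids.append(resseq)
                rnames.append(residue.resname)
                anames.append(atom.get_name())
                elems.append((atom.element or atom.get_name()[:1]).strip().upper())
                xyz.append(atom.coord)
    if not rids:
        raise ValueError("no ATOM records found")
    return Structure(
        residue_ids=np.array(rids),
        residue_names=rnames,
        atom_names=anames,
        elements=elems,
        coords=np.array(xyz, dtype=float),
        chain_id=chosen_chain or "A",
    )


def _parse_models(path: Union[str, os.PathLike]):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    return list(structure)


def read_structure(
    path: Union[str, os.PathLike],
    model_index: int = 1,
    chain_id: Optional[str] = None,
) -> Structure:
    """Read one MODEL of a PDB file.

    ``model_index`` is 1-based over the MODEL blocks in file order;
    single-model files ignore it. HETATM records (ligands, waters) are
    skipped.
    """
    models = _parse_models(path)
    if not models:
        raise ValueError(f"{path}: no models found")
    if len(models) == 1:
        model = models[0]
    else:
        if not (1 <= model_index <= len(models)):
            raise IndexError(
                f"model_index {model_index} out of range for {len(models)} models"
            )
        model = models[model_index - 1]
    return _structure_from_model(model, chain_id)


_TRAJECTORY_ADAPTERS: Dict[str, Callable] = {}


def register_trajectory_adapter(name: str, reader: Callable) -> None:
    """Register a reader for a non-PDB trajectory format.

    ``reader(path, topology) -> (frames (F,N,3) Å, frame_times ns or None)``.
    This keeps binary formats (DCD/XTC, ...) pluggable without making
    them core dependencies.
    """
    _TRAJECTORY_ADAPTERS[name] = reader


def read_trajectory(
    path_or_paths: Union[str, os.PathLike, Sequence[Union[str, os.PathLike]]],
    topology: Optional[Structure] = None,
    frame_interval_ns: Optional[float] = None,
    format: str = "pdb",
    chain_id: Optional[str] = None,
) -> Trajectory:
    """Read a multi-model PDB (or adapter-handled) trajectory.

    Frames keep their stored order; several paths concatenate in the
    given order. Frame times come from ``frame_interval_ns`` when
    supplied, otherwise they default to the frame index (so windowing
    in "ns" degrades gracefully to windowing in frames).
    """
    paths = (
        [path_or_paths]
        if isinstance(path_or_paths, (str, os.PathLike))
        else list(path_or_paths)
    )
    if format != "pdb":
        if format not in _TRAJECTORY_ADAPTERS:
            raise ValueError(f"no trajectory adapter registered for format {format!r}")
        if topology is None:
            raise ValueError("adapter formats require an explicit topology")
        all_frames, times = [], None
        for p in paths:
            frames, times = _TRAJECTORY_ADAPTERS[format](p, topology)
            all_frames.append(np.asarray(frames, dtype=float))
        frames = np.concatenate(all_frames, axis=0)
    else:
        frames_list = []
        for p in paths:
            models = _parse_models(p)
            if not models:
                raise ValueError(f"{p}: zero frames")
            for model in models:
                s = _structure_from_model(model, chain_id)
                if topology is None:
                    topology = s
                if s.n_atoms != topology.n_atoms:
                    raise ValueError(
                        f"{p}: frame atom count {s.n_atoms} does not match "
                        f"topology atom count {topology.n_atoms}"
                    )
                frames_list.append(s.coords)
        frames = np.stack(frames_list, axis=0)
        times = None
    if frames.shape[0] == 0:
        raise ValueError("zero frames read")
    if frame_interval_ns is not None:
        frame_times = np.arange(frames.shape[0]) * float(frame_interval_ns)
    elif times is not None:
        frame_times = np.asarray(times, dtype=float)
    else:
        frame_times = np.arange(frames.shape[0], dtype=float)
    assert topology is not None
    return Trajectory(topology=topology, frames=frames, frame_times=frame_times)


def _build_entity(traj: Trajectory):
    """Assemble a Bio.PDB entity with one model per frame."""
    topo = traj.topology
    builder = StructureBuilder()
    builder.init_structure("traj")
    for f in range(traj.n_frames):
        builder.init_model(f, f)
        builder.init_chain(topo.chain_id)
        builder.init_seg("    ")
        current_res = None
        for a in range(topo.n_atoms):
            rid = int(topo.residue_ids[a])
            if rid != current_res:
                builder.init_residue(topo.residue_names[a], " ", rid, " ")
                current_res = rid
            builder.init_atom(
                topo.atom_names[a],
                traj.frames[f, a].astype(np.float32),
                0.0,
                1.0,
                " ",
                topo.atom_names[a].ljust(4)[:4],
                a + 1,
                element=topo.elements[a],
            )
    return builder.get_structure()


def write_trajectory(traj: Trajectory, path: Union[str, os.PathLike]) -> None:
    """Write a trajectory as a multi-model PDB (3-decimal Å text)."""
    io = PDBIO()
    io.set_structure(_build_entity(traj))
    io.save(str(path), write_end=True)


def write_structure(structure: Structure, path: Union[str, os.PathLike]) -> None:
    traj = Trajectory(
        topology=structure,
        frames=structure.coords[None, :, :],
        frame_times=np.array([0.0]),
    )
    write_trajectory(traj, path)


# ---------------------------------------------------------------------------
# Selections


def select_atoms(structure: Structure, mode: str = "all") -> AtomSelection:
    """Select atoms by role.

    ``calpha`` returns exactly one CA per residue (error if a residue
    lacks one); ``heavy`` drops hydrogens by element; ``all`` is the
    identity selection.
    """
    if structure.n_atoms == 0:
        raise ValueError("empty structure")
    if mode == "all":
        return AtomSelection(np.arange(structure.n_atoms), "all")
    if mode == "heavy":
        idx = [
            i for i, e in enumerate(structure.elements) if e.upper() not in ("H", "D")
        ]
        return AtomSelection(np.array(idx, dtype=int), "heavy")
    if mode == "calpha":
        seen: Dict[int, int] = {}
        for i, (rid, name) in enumerate(
            zip(structure.residue_ids, structure.atom_names)
        ):
            if name.strip() == "CA" and int(rid) not in seen:
                seen[int(rid)] = i
        missing = [
            int(r) for r in structure.residue_index_list if int(r) not in seen
        ]
        if missing:
            raise ValueError(f"residues without CA atom: {missing}")
        idx = [seen[int(r)] for r in structure.residue_index_list]
        return AtomSelection(np.array(idx, dtype=int), "calpha")
    raise ValueError(f"unknown selection mode {mode!r}")
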