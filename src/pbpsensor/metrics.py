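"""State metrics for hinge-type binding proteins.

RMSD against a reference conformation classifies replicate simulations
as open or closed; per-residue RMSF and four-Cα pseudo-dihedral profiles
are differenced between the two state ensembles to locate regions of
conformational change. All angular work is done with circular means and
wrapped differences, since hinge residues routinely sit near ±180°.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .config import AnalysisConfig
from .trajectory import AtomSelection, Structure, Trajectory, select_atoms

__all__ = [
    "RmsdSeries",
    "StateLabel",
    "State",
    "ResidueProfile",
    "superpose",
    "rmsd_series",
    "classify_state",
    "ca_pseudo_dihedral",
    "dihedral_profile",
    "delta_dihe_structures",
    "dihedral_window_profile",
    "rmsf_profile",
    "ensemble_delta",
]


class State(str, Enum):
    OPEN = "open"
    CLOSED = "closed"


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) of a trajectory against a fixed reference."""

    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.values) != len(self.frame_times):
            raise ValueError("values and frame_times length mismatch")
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD values must be non-negative")

    def tail_mean(self, window_ns: Optional[float]) -> float:
        if window_ns is None:
            return float(np.mean(self.values))
        span = self.frame_times[-1] - self.frame_times[0]
        if span < window_ns:
            raise ValueError(
                f"series spans {span} ns, shorter than window {window_ns} ns"
            )
        t0 = self.frame_times[-1] - window_ns
        return float(np.mean(self.values[self.frame_times >= t0 - 1e-9]))


@dataclass
class StateLabel:
    state: State
    mean_last_window: float  # Å

    @property
    def is_closed(self) -> bool:
        return self.state is State.CLOSED


@dataclass
class ResidueProfile:
    """One value per residue for which the metric is defined."""

    residue_ids: np.ndarray
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_ids) != len(self.values):
            raise ValueError("residue_ids and values length mismatch")

    def as_dict(self) -> Dict[int, float]:
        return {int(r): float(v) for r, v in zip(self.residue_ids, self.values)}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("residue_index\tmetric\tvalue\n")
            for r, v in zip(self.residue_ids, self.values):
                fh.write(f"{int(r)}\t{self.metric}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Superposition and RMSD


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with
    ``fitted = mobile @ rotation.T + translation`` and ``rmsd`` the
    post-fit value in Å. Degenerate point sets (all collinear or
    coincident) are rejected: the optimal rotation is not unique there.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    mob_c = mobile - mob_mean
    ref_c = reference - ref_mean
    sv = np.linalg.svd(mob_c.T @ ref_c, compute_uv=False)
    scale = max(float(np.linalg.norm(mob_c)) * float(np.linalg.norm(ref_c)), 1e-30)
    if sv[1] <= 1e-12 * scale:
        raise ValueError("degenerate point set: superposition not unique")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # planar sets trigger a benign notice
        rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    translation = ref_mean - R @ mob_mean
    rmsd = float(rssd) / np.sqrt(mobile.shape[0])
    return R, translation, rmsd


def _frame_rmsd(
    frame: np.ndarray, reference: np.ndarray, fit: bool
) -> float:
    if fit:
        return superpose(frame, reference)[2]
    return float(np.sqrt(np.mean(np.sum((frame - reference) ** 2, axis=1))))


def rmsd_series(
    trajectory: Trajectory,
    reference: Structure,
    selection: Optional[AtomSelection] = None,
    fit: bool = True,
) -> RmsdSeries:
    """Per-frame (optionally superposed) RMSD against ``reference``."""
    if selection is None:
        selection = select_atoms(trajectory.topology, "calpha")
    if len(selection) == 0:
        raise ValueError("empty selection")
    ref = reference.coords[selection.indices]
    vals = np.array(
        [
            _frame_rmsd(trajectory.frames[f][selection.indices], ref, fit)
            for f in range(trajectory.n_frames)
        ]
    )
    return RmsdSeries(values=vals, frame_times=trajectory.frame_times)


def classify_state(
    series: RmsdSeries, config: Optional[AnalysisConfig] = None
) -> StateLabel:
    """Label a simulation closed/open from its trailing-window mean RMSD.

    Closed iff the mean over the final window is strictly below the
    threshold (default 2.5 Å over the last 50 ns); a mean exactly at the
    threshold is called open.
    """
    config = config or AnalysisConfig()
    mean_last = series.tail_mean(config.window_ns)
    state = State.CLOSED if mean_last < config.rmsd_threshold else State.OPEN
    return StateLabel(state=state, mean_last_window=mean_last)


# ---------------------------------------------------------------------------
# Pseudo-dihedrals


def _torsion_deg(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> np.ndarray:
    """Torsion of four points in degrees in (-180, 180], cis = 0.

    Vectorised over leading axes.
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    if np.any(norm1 < 1e-10) or np.any(norm2 < 1e-10):
        raise ValueError("colinear points: torsion undefined")
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2u, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # IUPAC-style convention here maps the planar trans arrangement to 180;
    # fold the single excluded value -180 onto +180.
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return ang


def _ca_map(structure: Structure) -> Dict[int, np.ndarray]:
    rids, coords = structure.ca_coords()
    return {int(r): c for r, c in zip(rids, coords)}


def ca_pseudo_dihedral(structure: Structure, i: int) -> float:
    """Pseudo-dihedral at residue ``i``: torsion of Cα(i-1..i+2), degrees.

    Undefined for the first residue and the last two of a chain.
    """
    ca = _ca_map(structure)
    quad = [i - 1, i, i + 1, i + 2]
    missing = [r for r in quad if r not in ca]
    if missing:
        raise IndexError(f"residues without CA for dihedral at {i}: {missing}")
    return float(_torsion_deg(*(ca[r] for r in quad)))


def _dihedral_residues(residue_ids: Sequence[int]) -> List[int]:
    present = set(int(r) for r in residue_ids)
    return sorted(
        r for r in present if {r - 1, r + 1, r + 2} <= present
    )


def dihedral_profile(structure: Structure, metric: str = "dihe") -> ResidueProfile:
    """Pseudo-dihedral at every residue where the four Cα exist."""
    ca = _ca_map(structure)
    rids = _dihedral_residues(list(ca))
    vals = [float(_torsion_deg(ca[r - 1], ca[r], ca[r + 1], ca[r + 2])) for r in rids]
    return ResidueProfile(np.array(rids), np.array(vals), metric)


def wrap_angle(a) -> np.ndarray:
    """Wrap angle(s) in degrees into (-180, 180]."""
    w = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(np.isclose(w, -180.0), 180.0, w)


def circular_mean_deg(angles: np.ndarray, axis=None) -> np.ndarray:
    """Circular mean of angles in degrees."""
    rad = np.radians(np.asarray(angles, dtype=float))
    s = np.mean(np.sin(rad), axis=axis)
    c = np.mean(np.cos(rad), axis=axis)
    return np.degrees(np.arctan2(s, c))


def delta_dihe_structures(
    struct_a: Structure, struct_b: Structure, metric: str = "delta_dihe_crys"
) -> ResidueProfile:
    """Per-residue |wrapped Δ| of the pseudo-dihedral between two
    conformations with identical numbering; values in [0°, 180°]."""
    pa = dihedral_profile(struct_a)
    pb = dihedral_profile(struct_b)
    if not np.array_equal(pa.residue_ids, pb.residue_ids):
        raise ValueError("residue numbering mismatch between structures")
    delta = np.abs(wrap_angle(pa.values - pb.values))
    return ResidueProfile(pa.residue_ids, delta, metric)


def dihedral_window_profile(
    trajectory: Trajectory, window_ns: Optional[float] = None
) -> ResidueProfile:
    """Circular mean of each residue's pseudo-dihedral over the trailing
    window (one value per residue, degrees)."""
    sel = select_atoms(trajectory.topology, "calpha")
    rid_order = trajectory.topology.residue_ids[sel.indices]
    pos = {int(r): k for k, r in enumerate(rid_order)}
    rids = _dihedral_residues(list(pos))
    frames = trajectory.tail_window(window_ns)
    ca = trajectory.frames[frames][:, sel.indices, :]  # (F, R, 3)
    i0 = np.array([pos[r - 1] for r in rids])
    i1 = np.array([pos[r] for r in rids])
    i2 = np.array([pos[r + 1] for r in rids])
    i3 = np.array([pos[r + 2] for r in rids])
    ang = _torsion_deg(ca[:, i0], ca[:, i1], ca[:, i2], ca[:, i3])  # (F, nres)
    return ResidueProfile(np.array(rids), circular_mean_deg(ang, axis=0), "dihe_md")


# ---------------------------------------------------------------------------
# RMSF


def rmsf_profile(
    trajectory: Trajectory,
    selection: Optional[AtomSelection] = None,
    window_ns: Optional[float] = None,
    fit: bool = True,
) -> ResidueProfile:
    """Per-residue Cα RMSF (Å) over the trailing window.

    With ``fit=True`` every frame is first superposed onto the
    window-mean structure (one refinement pass seeded from the first
    window frame), making the profile invariant to rigid-body drift.
    """
    if selection is None:
        selection = select_atoms(trajectory.topology, "calpha")
    if len(selection) == 0:
        raise ValueError("empty selection")
    frames_idx = trajectory.tail_window(window_ns)
    X = trajectory.frames[frames_idx][:, selection.indices, :].copy()
    if fit:
        ref = X[0]
        fitted = np.empty_like(X)
        for f in range(X.shape[0]):
            R, t, _ = superpose(X[f], ref)
            fitted[f] = X[f] @ R.T + t
        mean1 = fitted.mean(axis=0)
        for f in range(X.shape[0]):
            R, t, _ = superpose(X[f], mean1)
            fitted[f] = X[f] @ R.T + t
        X = fitted
    mean = X.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    rids = trajectory.topology.residue_ids[selection.indices]
    return ResidueProfile(rids, rmsf, "rmsf")


# ---------------------------------------------------------------------------
# Ensemble differencing


def ensemble_delta(
    closed_profiles: Sequence[ResidueProfile],
    open_profiles: Sequence[ResidueProfile],
    metric: str,
) -> ResidueProfile:
    """Closed-ensemble mean minus open-ensemble mean, per residue.

    ``metric`` is ``"rmsf"`` (plain arithmetic means, signed result, Å)
    or ``"dihedral"`` (circular means per state, wrapped difference,
    absolute value, degrees).
    """
    if not closed_profiles or not open_profiles:
        raise ValueError("both state groups need at least one profile")
    rids = closed_profiles[0].residue_ids
    for p in list(closed_profiles) + list(open_profiles):
        if not np.array_equal(p.residue_ids, rids):
            raise ValueError("profiles must share a common residue set")
    closed = np.stack([p.values for p in closed_profiles])
    open_ = np.stack([p.values for p in open_profiles])
    if metric == "rmsf":
        delta = closed.mean(axis=0) - open_.mean(axis=0)
        tag = "delta_rmsf"
    elif metric == "dihedral":
        mc = circular_mean_deg(closed, axis=0)
        mo = circular_mean_deg(open_, axis=0)
        delta = np.abs(wrap_angle(mc - mo))
        tag = "delta_dihe_md"
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return ResidueProfile(rids, delta, tag)
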