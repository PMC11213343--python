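"""Hysteresis residue contacts and Pearson-vs-time matrices.

A residue pair is "in contact" once its closest-atom distance drops
below ``r_start`` and stays so until the distance exceeds ``r_end``
(the dual cutoff suppresses flicker from momentary separations). For
every pair that is ever in contact, the minimum distance — truncated at
``r_end`` so that far-apart excursions carry no weight — is correlated
with simulation time. Positive pixels mark contacts present early
(closed state), negative pixels contacts formed late (open state).

Default thresholds are 5.0 / 8.0 Å. These are sometimes quoted as
"0.5 / 0.8" in contact-analysis tooling that works in nm; sub-Ångström
closest-atom cutoffs would be physically impossible, so this package
treats such figures as nm and keeps Å internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .config import AnalysisConfig
from .trajectory import Structure, Trajectory, select_atoms

__all__ = [
    "PairDistanceSeries",
    "ContactSeries",
    "PearsonMatrix",
    "pair_min_distance_series",
    "hysteresis_contact_series",
    "pearson_vs_time",
    "build_pearson_matrix",
    "mean_pearson_matrix",
    "two_structure_matrix",
    "residue_min_distance_frames",
]


@dataclass
class PairDistanceSeries:
    """Per-frame closest-atom distance (Å) for one residue pair i < j."""

    pair: Tuple[int, int]
    distances: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        i, j = self.pair
        if i >= j:
            raise ValueError(f"require i < j, got {self.pair}")
        self.distances = np.asarray(self.distances, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")
        if len(self.distances) != len(self.frame_times):
            raise ValueError("distances and frame_times length mismatch")


@dataclass
class ContactSeries:
    """Boolean in-contact flags for one residue pair under hysteresis."""

    pair: Tuple[int, int]
    in_contact: np.ndarray

    def __post_init__(self) -> None:
        self.in_contact = np.asarray(self.in_contact, dtype=bool)

    @property
    def ever_in_contact(self) -> bool:
        return bool(np.any(self.in_contact))


@dataclass
class PearsonMatrix:
    """Symmetric per-residue-pair correlation matrix in [-1, 1].

    ``residue_ids[k]`` is the 1-based residue index of row/column ``k``.
    Excluded pairs (never in contact, sequence neighbours, diagonal)
    hold exactly 0.
    """

    values: np.ndarray
    residue_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("matrix must be square")
        if len(self.residue_ids) != n:
            raise ValueError("residue_ids length must match matrix size")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("Pearson values must lie in [-1, 1]")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def pixel(self, res_i: int, res_j: int) -> float:
        pos = {int(r): k for k, r in enumerate(self.residue_ids)}
        return float(self.values[pos[res_i], pos[res_j]])

    def write_tsv(self, path) -> None:
        """Dense TSV; header line carries size and first residue id."""
        with open(path, "w") as fh:
            fh.write(f"# n={self.n}\tresidue_offset={int(self.residue_ids[0])}\n")
            for row in self.values:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")

    def write_long_tsv(self, path, nonzero_only: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write("res_i\tres_j\tvalue\n")
            for a in range(self.n):
                for b in range(a + 1, self.n):
                    v = self.values[a, b]
                    if nonzero_only and v == 0.0:
                        continue
                    fh.write(
                        f"{int(self.residue_ids[a])}\t{int(self.residue_ids[b])}"
                        f"\t{v:.6g}\n"
                    )

    @classmethod
    def read_tsv(cls, path) -> "PearsonMatrix":
        with open(path) as fh:
            header = fh.readline()
            fields = dict(
                item.split("=") for item in header.lstrip("# ").split()
            )
            n = int(fields["n"])
            offset = int(fields["residue_offset"])
            values = np.loadtxt(fh, ndmin=2)
        if values.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {values.shape}")
        return cls(values=values, residue_ids=np.arange(offset, offset + n))


# ---------------------------------------------------------------------------
# Distances


def _residue_atom_groups(
    structure: Structure, selection_mode: str
) -> Tuple[np.ndarray, List[np.ndarray]]:
    sel = select_atoms(structure, selection_mode)
    rids_sel = structure.residue_ids[sel.indices]
    order = structure.residue_index_list
    groups = [sel.indices[rids_sel == r] for r in order]
    return order, groups


def residue_min_distance_frames(
    trajectory: Trajectory, selection_mode: str = "heavy"
) -> Tuple[np.ndarray, np.ndarray]:
    """(residue_ids, D) with D of shape (n_frames, n_res, n_res): per
    frame minimum inter-residue atom distance (Å). Diagonal is 0."""
    order, groups = _residue_atom_groups(trajectory.topology, selection_mode)
    empty = [int(order[k]) for k, g in enumerate(groups) if len(g) == 0]
    if empty:
        raise ValueError(f"residues with empty atom selection: {empty}")
    nres = len(order)
    one_atom = all(len(g) == 1 for g in groups)
    if one_atom:
        idx = np.array([g[0] for g in groups])
        pts = trajectory.frames[:, idx, :]  # (F, R, 3)
        diff = pts[:, :, None, :] - pts[:, None, :, :]
        D = np.sqrt(np.sum(diff**2, axis=-1))
    else:
        F = trajectory.n_frames
        D = np.zeros((F, nres, nres))
        for f in range(F):
            coords = trajectory.frames[f]
            for a in range(nres):
                for b in range(a + 1, nres):
                    d = cdist(coords[groups[a]], coords[groups[b]]).min()
                    D[f, a, b] = D[f, b, a] = d
    return order, D


def pair_min_distance_series(
    trajectory: Trajectory,
    res_i: int,
    res_j: int,
    selection_mode: str = "heavy",
) -> PairDistanceSeries:
    """Closest-atom distance between residues ``res_i`` and ``res_j``
    in every frame (minimum over all selected atom pairs)."""
    if res_i == res_j:
        raise ValueError("residue pair must be distinct")
    i, j = sorted((res_i, res_j))
    order, groups = _residue_atom_groups(trajectory.topology, selection_mode)
    pos = {int(r): k for k, r in enumerate(order)}
    for r in (i, j):
        if r not in pos:
            raise KeyError(f"residue {r} not in topology")
    gi, gj = groups[pos[i]], groups[pos[j]]
    if len(gi) == 0 or len(gj) == 0:
        raise ValueError("empty residue atom selection")
    dists = np.array(
        [
            cdist(trajectory.frames[f][gi], trajectory.frames[f][gj]).min()
            for f in range(trajectory.n_frames)
        ]
    )
    return PairDistanceSeries(
        pair=(i, j), distances=dists, frame_times=trajectory.frame_times
    )


# ---------------------------------------------------------------------------
# Hysteresis contacts and correlation


def hysteresis_contact_series(
    distances: np.ndarray,
    config: Optional[AnalysisConfig] = None,
    pair: Tuple[int, int] = (1, 2),
) -> ContactSeries:
    """Dual-cutoff contact state machine.

    Starts out of contact; enters at the first frame with
    ``d < r_start``; leaves at the first later frame with
    ``d > r_end``; re-entry requires dropping below ``r_start`` again.
    """
    config = config or AnalysisConfig()
    d = np.asarray(distances, dtype=float)
    flags = np.zeros(len(d), dtype=bool)
    state = False
    for k, dist in enumerate(d):
        if not state and dist < config.r_start:
            state = True
        elif state and dist > config.r_end:
            state = False
        flags[k] = state
    return ContactSeries(pair=pair, in_contact=flags)


def pearson_vs_time(
    distances: np.ndarray,
    frame_times: np.ndarray,
    config: Optional[AnalysisConfig] = None,
    mode: str = "distance",
) -> float:
    """Pearson correlation of a pair's distance signal with time.

    ``mode="distance"`` (default) correlates ``min(d, r_end)`` with
    time: a pair in contact early that separates gives +1. The
    ``"indicator"`` variant correlates the hysteresis contact flag with
    time and is negated so the sign convention matches (positive =
    early/closed-state contact). Either variable having zero variance
    yields 0 by convention.
    """
    config = config or AnalysisConfig()
    d = np.asarray(distances, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 frames")
    if mode == "distance":
        x = np.minimum(d, config.r_end)
        sign = 1.0
    elif mode == "indicator":
        x = hysteresis_contact_series(d, config).in_contact.astype(float)
        sign = -1.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    xc = x - x.mean()
    tc = t - t.mean()
    sx = np.sqrt(np.sum(xc**2))
    st = np.sqrt(np.sum(tc**2))
    if sx == 0.0 or st == 0.0:
        return 0.0
    r = float(np.sum(xc * tc) / (sx * st))
    # exactly (anti)linear signals accumulate ~1e-16 rounding; restore the
    # exact bound so perfectly monotone-linear pairs report ±1
    if abs(r) > 1.0 - 1e-12:
        r = np.sign(r)
    return sign * min(1.0, max(-1.0, r))


def build_pearson_matrix(
    trajectory: Trajectory,
    config: Optional[AnalysisConfig] = None,
    selection_mode: str = "heavy",
    mode: str = "distance",
) -> PearsonMatrix:
    """Pearson-vs-time matrix over all ever-in-contact residue pairs.

    Pairs within ``neighbor_exclusion`` sequence positions, and pairs
    never in contact under the hysteresis rule, hold 0.
    """
    config = config or AnalysisConfig()
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames")
    order, D = residue_min_distance_frames(trajectory, selection_mode)
    nres = len(order)
    values = np.zeros((nres, nres))
    t = trajectory.frame_times
    for a in range(nres):
        for b in range(a + 1, nres):
            if abs(int(order[a]) - int(order[b])) <= config.neighbor_exclusion:
                continue
            d = D[:, a, b]
            if not hysteresis_contact_series(d, config).ever_in_contact:
                continue
            r = pearson_vs_time(d, t, config, mode=mode)
            values[a, b] = values[b, a] = r
    return PearsonMatrix(values=values, residue_ids=order)


def mean_pearson_matrix(matrices: Sequence[PearsonMatrix]) -> PearsonMatrix:
    """Pixel-wise arithmetic mean across per-simulation matrices."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape or not np.array_equal(
            m.residue_ids, first.residue_ids
        ):
            raise ValueError("matrices must share shape and residue numbering")
    mean = np.mean([m.values for m in matrices], axis=0)
    return PearsonMatrix(values=mean, residue_ids=first.residue_ids)


def two_structure_matrix(
    struct_a: Structure,
    struct_b: Structure,
    config: Optional[AnalysisConfig] = None,
    selection_mode: str = "heavy",
) -> PearsonMatrix:
    """Contact-change matrix from a single pair of conformations.

    The two structures are treated as a 2-frame trajectory, so every
    pixel is +1 (closer in A), -1 (closer in B) or 0 by construction.
    """
    if not np.array_equal(
        struct_a.residue_index_list, struct_b.residue_index_list
    ):
        raise ValueError("residue numbering mismatch between structures")
    config = config or AnalysisConfig()

    def _single(structure: Structure) -> Tuple[np.ndarray, np.ndarray]:
        traj = Trajectory(
            topology=structure,
            frames=structure.coords[None],
            frame_times=np.array([0.0]),
        )
        return residue_min_distance_frames(traj, selection_mode)

    order, DA = _single(struct_a)
    _, DB = _single(struct_b)
    nres = len(order)
    values = np.zeros((nres, nres))
    t = np.array([0.0, 1.0])
    for a in range(nres):
        for b in range(a + 1, nres):
            if abs(int(order[a]) - int(order[b])) <= config.neighbor_exclusion:
                continue
            d = np.array([DA[0, a, b], DB[0, a, b]])
            if not hysteresis_contact_series(d, config).ever_in_contact:
                continue
            values[a, b] = values[b, a] = pearson_vs_time(d, t, config)
    return PearsonMatrix(values=values, residue_ids=order)
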