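"""Synthetic fixtures: a toy two-lobe hinge protein and simulated plates.

The hinge fixture emulates, at desk scale, the opening motion of a
two-lobe binding protein: two rigid Cα strands face each other 4.5 Å
apart (in contact) and one lobe moves away on a monotone schedule, so
the facing residue pairs are exactly the contacts that change. The
generator returns the trajectory together with the ground-truth set of
changing-contact pairs and their expected Pearson signs, computed
geometrically from the noiseless coordinates — independently of the
contact-analysis code the fixture is used to test.

The default motion is a linearized (small-angle) hinge: lobe
separation grows proportionally to the opening angle, which makes each
facing pair's distance an affine function of time and its expected
Pearson correlation exactly +1 at zero noise. A finite-rotation mode
(``motion="rotation"``) swings the mobile lobe about the hinge pivot
instead; distances are then monotone but nonlinear in time, so only
the signs of the pixels are exact there.

The fixture is geometric, not physical: no force field, solvent,
ligand, or thermal kinetics — passing tests demonstrate correctness of
the analysis chain, not realism of the motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .trajectory import Structure, Trajectory

__all__ = [
    "HingeSpec",
    "HingeGroundTruth",
    "generate_hinge_trajectory",
    "fixture_config",
    "generate_plate_assay",
]

_CA_SPACING = 3.8  # Å, consecutive-residue Cα distance
_FACING_GAP = 4.5  # Å, inter-lobe gap at frame 0 (inside the 5 Å contact cutoff)


@dataclass
class HingeSpec:
    """Geometry and schedule of the toy hinge trajectory.

    ``opening_angle_schedule`` (degrees per frame, monotone for an
    opening fixture) defaults to a linear ramp 0..``max_angle_deg``.
    With the default ``arm`` of 8.6 Å the 20° ramp separates the lobes
    by 3.0 Å, keeping every designed contact inside the 8 Å hysteresis
    exit threshold for its whole lifetime.
    """

    residues_per_lobe: int = 12
    n_frames: int = 21
    frame_interval_ns: float = 0.1
    max_angle_deg: float = 20.0
    opening_angle_schedule: Optional[np.ndarray] = None
    noise_sigma: float = 0.0  # Å, isotropic Gaussian per atom per frame
    seed: int = 0
    arm: float = 8.6  # Å, effective lever arm of the hinge
    motion: str = "shear"  # "shear" (linearized) | "rotation"
    atoms_per_residue: int = 1  # 2 adds a CB-like atom, exercising all-pairs minima

    def schedule_deg(self) -> np.ndarray:
        if self.opening_angle_schedule is not None:
            sched = np.asarray(self.opening_angle_schedule, dtype=float)
            if len(sched) != self.n_frames:
                raise ValueError("schedule length must equal n_frames")
            return sched
        return np.linspace(0.0, self.max_angle_deg, self.n_frames)

    @property
    def n_residues(self) -> int:
        return 2 * self.residues_per_lobe + 2

    @property
    def hinge_residue_indices(self) -> Tuple[int, int]:
        m = self.residues_per_lobe
        return (m + 1, m + 2)

    @property
    def hinge_flank(self) -> Tuple[int, int]:
        """Last lobe-A residue and first lobe-B residue."""
        m = self.residues_per_lobe
        return (m, m + 3)


@dataclass
class HingeGroundTruth:
    """Exact changing-contact pairs and their expected Pearson signs."""

    designed_pairs: List[Tuple[int, int, int]]  # (i, j, sign), i < j
    hinge_flank: Tuple[int, int]

    @property
    def pair_set(self) -> set:
        return {(i, j) for i, j, _ in self.designed_pairs}


def _base_geometry(spec: HingeSpec) -> Tuple[np.ndarray, np.ndarray]:
    """(coords0, mobile_mask) for one atom per residue at frame 0."""
    m = spec.residues_per_lobe
    n = spec.n_residues
    coords = np.zeros((n, 3))
    mobile = np.zeros(n, dtype=bool)
    for r in range(1, m + 1):  # lobe A along +x
        coords[r - 1] = ((r - 1) * _CA_SPACING, 0.0, 0.0)
    hx = (m + 0.5) * _CA_SPACING  # hinge sits beyond both strand ends
    coords[m] = (hx, 1.5, 0.0)
    coords[m + 1] = (hx, 3.0, 0.0)
    for k in range(1, m + 1):  # lobe B antiparallel, facing lobe A
        coords[m + 1 + k] = ((m - k) * _CA_SPACING, _FACING_GAP, 0.0)
        mobile[m + 1 + k] = True
    return coords, mobile


def _frame_coords(spec: HingeSpec, coords0, mobile, theta_deg: float) -> np.ndarray:
    theta = np.radians(theta_deg)
    out = coords0.copy()
    if spec.motion == "shear":
        out[mobile, 1] += spec.arm * theta  # arc-length separation, linear in angle
    elif spec.motion == "rotation":
        m = spec.residues_per_lobe
        pivot = np.array([(m + 0.5) * _CA_SPACING, 2.25, 0.0])
        c, s = np.cos(-theta), np.sin(-theta)  # clockwise opens the lobes
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        out[mobile] = (coords0[mobile] - pivot) @ R.T + pivot
    else:
        raise ValueError(f"unknown motion {spec.motion!r}")
    return out


def _ground_truth(
    noiseless: np.ndarray, spec: HingeSpec, config: AnalysisConfig
) -> HingeGroundTruth:
    """Scan noiseless per-residue distance series for threshold crossings.

    A pair is a designed changing contact if it comes within ``r_start``
    in some frame and its r_end-truncated distance is not constant; the
    sign is +1 for separating pairs, -1 for approaching ones.
    """
    diff = noiseless[:, :, None, :] - noiseless[:, None, :, :]
    D = np.sqrt(np.sum(diff**2, axis=-1))  # (F, n, n)
    n = noiseless.shape[1]
    pairs: List[Tuple[int, int, int]] = []
    for a in range(n):
        for b in range(a + 1, n):
            if b - a <= config.neighbor_exclusion:
                continue
            d = D[:, a, b]
            if not np.any(d < config.r_start):
                continue
            trunc = np.minimum(d, config.r_end)
            if np.ptp(trunc) < 1e-9:
                continue
            sign = 1 if d[-1] > d[0] else -1
            pairs.append((a + 1, b + 1, sign))
    return HingeGroundTruth(designed_pairs=pairs, hinge_flank=spec.hinge_flank)


def generate_hinge_trajectory(
    spec: Optional[HingeSpec] = None,
    config: Optional[AnalysisConfig] = None,
) -> Tuple[Trajectory, HingeGroundTruth]:
    """Build the hinge trajectory and its exact contact ground truth.

    Ground truth is evaluated on the noiseless coordinates under the
    thresholds in ``config`` (defaults: 5/8 Å, neighbour exclusion 2).
    """
    spec = spec or HingeSpec()
    config = config or AnalysisConfig()
    coords0, mobile = _base_geometry(spec)
    sched = spec.schedule_deg()
    noiseless = np.stack(
        [_frame_coords(spec, coords0, mobile, th) for th in sched]
    )
    if np.min(
        np.linalg.norm(
            noiseless[0, mobile][:, None, :] - noiseless[0, ~mobile][None, :, :],
            axis=-1,
        )
    ) < 1.0:
        raise ValueError("invalid geometry: lobes overlap at frame 0")
    truth = _ground_truth(noiseless, spec, config)

    per_res = noiseless
    if spec.atoms_per_residue == 2:
        # add a CB-like atom 1 Å above each Cα; facing-pair minima unchanged
        shifted = per_res + np.array([0.0, 0.0, 1.0])
        frames = np.concatenate(
            [
                np.stack([per_res[:, k], shifted[:, k]], axis=1)
                for k in range(spec.n_residues)
            ],
            axis=1,
        )
    elif spec.atoms_per_residue == 1:
        frames = per_res
    else:
        raise ValueError("atoms_per_residue must be 1 or 2")

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(0.0, spec.noise_sigma, size=frames.shape)

    napr = spec.atoms_per_residue
    residue_ids = np.repeat(np.arange(1, spec.n_residues + 1), napr)
    atom_names = (["CA"] if napr == 1 else ["CA", "CB"]) * spec.n_residues
    topology = Structure(
        residue_ids=residue_ids,
        residue_names=["ALA"] * (spec.n_residues * napr),
        atom_names=atom_names,
        elements=["C"] * (spec.n_residues * napr),
        coords=frames[0],
        chain_id="A",
    )
    traj = Trajectory(
        topology=topology,
        frames=frames,
        frame_times=np.arange(spec.n_frames) * spec.frame_interval_ns,
    )
    return traj, truth


def fixture_config(spec: Optional[HingeSpec] = None) -> AnalysisConfig:
    """Analysis parameters scaled to the toy hinge.

    The toy system is two orders of magnitude smaller and shorter than
    a real binding-protein simulation, so the trailing window is half
    the fixture span, the open/closed RMSD cut is 1.0 Å (the toy's
    opening shifts whole-molecule Cα RMSD by ~1.5 Å, not the ~4 Å of a
    370-residue protein), and the cluster percentile is 90 (the toy
    matrix yields a handful of clusters, not hundreds).
    """
    spec = spec or HingeSpec()
    span = (spec.n_frames - 1) * spec.frame_interval_ns
    return AnalysisConfig(
        rmsd_threshold=1.0,
        window_ns=span / 2.0,
        percentile=90.0,
        seed=spec.seed,
    )


def generate_plate_assay(
    true_dff0: Dict[str, Dict[float, float]],
    f0_level: float = 1000.0,
    background: float = 100.0,
    noise_sigma: float = 20.0,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
    control_label: str = "pET28a",
) -> pd.DataFrame:
    """Simulate a plate-reader table with known true ΔF/F0 per construct.

    Each reading is ``background + f0_level * (1 + ΔF/F0(conc)) +
    N(0, noise_sigma)`` (ΔF/F0 is 0 at 0 mM); an empty-vector control
    series reads ``background + noise``. Three biological × three
    technical replicates per condition by default, mirroring standard
    plate practice.
    """
    if f0_level <= 0:
        raise ValueError("f0_level must be positive")
    rng = np.random.default_rng(seed)
    concs = sorted({0.0} | {float(c) for d in true_dff0.values() for c in d})
    rows = []

    def _emit(construct: str, conc: float, level: float) -> None:
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                noise = rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
                rows.append(
                    {
                        "construct": construct,
                        "maltose_mM": conc,
                        "biological_rep": bio,
                        "technical_rep": tech,
                        "fluorescence": level + noise,
                    }
                )

    for construct, dmap in true_dff0.items():
        for conc in concs:
            dff0 = 0.0 if conc == 0.0 else float(dmap.get(conc, 0.0))
            _emit(construct, conc, background + f0_level * (1.0 + dff0))
    for conc in concs:
        _emit(control_label, conc, background)
    return pd.DataFrame(rows)
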