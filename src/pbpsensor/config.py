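"""Analysis configuration shared across the pipeline stages.

All residue indices in this package are 1-based, matching the numbering
used in structural-biology literature for the maltose binding protein
(e.g. residues 170, 233, 348).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Optional


@dataclass
class AnalysisConfig:
    """Tunable parameters for the contact-hotspot biosensor pipeline.

    Parameters
    ----------
    rmsd_threshold : float
        Mean-RMSD cutoff in Å separating closed (< threshold) from open
        (>= threshold) simulations.
    window_ns : float
        Length in ns of the trailing trajectory window over which state
        classification, RMSF and dihedral averages are computed.
    r_start : float
        Closest-atom distance in Å below which a residue contact forms.
    r_end : float
        Closest-atom distance in Å above which an existing contact is
        terminated (hysteresis: ``r_start < r_end`` suppresses flicker).
    percentile : float
        Percentile (0-100, exclusive) used to retain the most extreme
        contact-change clusters, peaks and valleys ranked separately.
    insertion_stride : int
        Spacing in residues between candidate effector insertion sites
        enumerated inside a hotspot residue range.
    viability_threshold : float
        |ΔF/F0| above which a sensor construct is called viable.
    neighbor_exclusion : int
        Sequence-neighbour band half-width: pairs with ``|i - j|`` at or
        below this are excluded from contact analysis (trivially in
        permanent contact).
    seed : int, optional
        Seed forwarded to any stochastic component (synthetic fixtures).
    """

    rmsd_threshold: float = 2.5
    window_ns: float = 50.0
    r_start: float = 5.0
    r_end: float = 8.0
    percentile: float = 99.0
    insertion_stride: int = 3
    viability_threshold: float = 0.25
    neighbor_exclusion: int = 2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.r_start < self.r_end):
            raise ValueError(
                f"require 0 < r_start < r_end, got {self.r_start}, {self.r_end}"
            )
        if not (0.0 < self.percentile < 100.0):
            raise ValueError(f"percentile must be in (0, 100), got {self.percentile}")
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be positive")
        if self.window_ns <= 0:
            raise ValueError("window_ns must be positive")
        if self.insertion_stride < 1:
            raise ValueError("insertion_stride must be >= 1")
        if self.neighbor_exclusion < 0:
            raise ValueError("neighbor_exclusion must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
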