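"""Cluster extraction and percentile filtering of contact-change maps.

Contiguous same-sign regions of the mean Pearson matrix — peaks
(positive, closed-state contacts) and valleys (negative, open-state
contacts) — are labelled with 8-connectivity on the strict upper
triangle, scored by mean / median / max-absolute pixel value, and the
most extreme clusters of each sign are retained. Retained clusters
propose effector insertion residue ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.measure import label as cc_label

from .config import AnalysisConfig
from .contacts import PearsonMatrix

__all__ = [
    "Cluster",
    "HotspotReport",
    "extract_clusters",
    "cluster_statistics",
    "percentile_filter",
    "hotspot_residues",
    "enumerate_insertion_sites",
    "build_hotspot_report",
]


@dataclass
class Cluster:
    """A contiguous same-sign region of the upper-triangle matrix.

    ``pixels`` are (res_i, res_j) with res_i < res_j, 1-based.
    """

    sign: int  # +1 peak, -1 valley
    pixels: List[Tuple[int, int]]
    mean: float
    median: float
    max_abs: float

    @property
    def size(self) -> int:
        return len(self.pixels)

    @property
    def residue_span_i(self) -> Tuple[int, int]:
        xs = [p[0] for p in self.pixels]
        return (min(xs), max(xs))

    @property
    def residue_span_j(self) -> Tuple[int, int]:
        ys = [p[1] for p in self.pixels]
        return (min(ys), max(ys))

    @property
    def residue_union(self) -> List[int]:
        return sorted({r for p in self.pixels for r in p})

    def to_dict(self) -> dict:
        return {
            "sign": self.sign,
            "n_pixels": self.size,
            "mean": self.mean,
            "median": self.median,
            "max_abs": self.max_abs,
            "residue_span_i": list(self.residue_span_i),
            "residue_span_j": list(self.residue_span_j),
            "residue_union": self.residue_union,
        }


def cluster_statistics(
    pixels: Sequence[Tuple[int, int]], matrix: PearsonMatrix
) -> Tuple[float, float, float]:
    """(mean, median, max|v|) of the matrix values at ``pixels``."""
    if not pixels:
        raise ValueError("empty cluster")
    vals = np.array([matrix.pixel(i, j) for i, j in pixels])
    return float(vals.mean()), float(np.median(vals)), float(np.abs(vals).max())


def extract_clusters(matrix: PearsonMatrix) -> List[Cluster]:
    """8-connected components of same-sign nonzero pixels.

    Operates on the strict upper triangle (the matrix is symmetric, so
    the lower triangle would only mirror every cluster); zero pixels
    separate clusters, and diagonal adjacency joins them.
    """
    V = matrix.values
    n = matrix.n
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    clusters: List[Cluster] = []
    for sign in (1, -1):
        mask = upper & ((V > 0) if sign > 0 else (V < 0))
        labels = cc_label(mask, connectivity=2)
        for lab in range(1, labels.max() + 1):
            rows, cols = np.nonzero(labels == lab)
            pixels = [
                (int(matrix.residue_ids[a]), int(matrix.residue_ids[b]))
                for a, b in zip(rows, cols)
            ]
            pixels.sort()
            mean, median, max_abs = cluster_statistics(pixels, matrix)
            clusters.append(
                Cluster(
                    sign=sign,
                    pixels=pixels,
                    mean=mean,
                    median=median,
                    max_abs=max_abs,
                )
            )
    clusters.sort(key=lambda c: (-c.sign, c.pixels[0]))
    return clusters


def percentile_filter(
    clusters: Sequence[Cluster], percentile: float = 99.0
) -> List[Cluster]:
    """Keep clusters extreme in mean, median AND max-absolute value.

    Peaks and valleys are ranked separately; valleys compare on
    |mean| and |median| so "top" means most extreme for both signs.
    Thresholds are linearly interpolated percentiles of each statistic
    within the sign group, and retention requires meeting all three
    simultaneously.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    retained: List[Cluster] = []
    for sign in (1, -1):
        group = [c for c in clusters if c.sign == sign]
        if not group:
            continue
        means = np.array([abs(c.mean) for c in group])
        medians = np.array([abs(c.median) for c in group])
        maxes = np.array([c.max_abs for c in group])
        thr = (
            np.percentile(means, percentile),
            np.percentile(medians, percentile),
            np.percentile(maxes, percentile),
        )
        eps = 1e-12  # guard float noise at the singleton/self-threshold boundary
        retained.extend(
            c
            for c, m, md, mx in zip(group, means, medians, maxes)
            if m >= thr[0] - eps and md >= thr[1] - eps and mx >= thr[2] - eps
        )
    retained.sort(key=lambda c: (-c.sign, c.pixels[0]))
    return retained


def hotspot_residues(
    cluster: Cluster,
) -> Tuple[Tuple[int, int], Tuple[int, int], List[int]]:
    """(span_i, span_j, sorted residue union) of a cluster."""
    if not cluster.pixels:
        raise ValueError("empty cluster")
    return cluster.residue_span_i, cluster.residue_span_j, cluster.residue_union


def enumerate_insertion_sites(start: int, end: int, stride: int = 3) -> List[int]:
    """Candidate insertion sites: every ``stride`` residues from
    ``start``, always including ``end``.

    E.g. 205-217 at stride 3 gives [205, 208, 211, 214, 217].
    """
    if start > end:
        raise ValueError(f"invalid range {start}-{end}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sites = list(range(start, end + 1, stride))
    if sites[-1] != end:
        sites.append(end)
    return sites


@dataclass
class HotspotReport:
    """Retained clusters plus candidate insertion sites per cluster."""

    clusters: List[Cluster]
    percentile: float
    insertion_sites: List[List[int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "percentile": self.percentile,
            "clusters": [
                {**c.to_dict(), "insertion_sites": sites}
                for c, sites in zip(self.clusters, self.insertion_sites)
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @property
    def all_sites(self) -> List[int]:
        return sorted({s for sites in self.insertion_sites for s in sites})


def build_hotspot_report(
    matrix: PearsonMatrix, config: Optional[AnalysisConfig] = None
) -> HotspotReport:
    """Cluster, filter, and enumerate insertion sites for a matrix.

    Sites are enumerated over each retained cluster's two residue
    spans (the i- and j-axis ranges) at ``insertion_stride``.
    """
    config = config or AnalysisConfig()
    clusters = extract_clusters(matrix)
    retained = percentile_filter(clusters, config.percentile)
    site_lists: List[List[int]] = []
    for c in retained:
        sites: set = set()
        for span in (c.residue_span_i, c.residue_span_j):
            sites.update(
                enumerate_insertion_sites(span[0], span[1], config.insertion_stride)
            )
        site_lists.append(sorted(sites))
    return HotspotReport(
        clusters=retained, percentile=config.percentile, insertion_sites=site_lists
    )
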