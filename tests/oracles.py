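"""Independent brute-force oracles used by unit and acceptance tests.

Each function re-derives a quantity by a different route than the
package implementation (explicit transition tables, textbook sums,
recursive flood fill, arccos-of-normals geometry) so that agreement is
a genuine cross-check, not a tautology.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

import numpy as np


def hysteresis_oracle(distances, r_start: float, r_end: float) -> np.ndarray:
    """Dual-cutoff contact flags via an explicit transition table."""
    transitions = {
        ("out", "below_start"): "in",
        ("out", "between"): "out",
        ("out", "above_end"): "out",
        ("in", "below_start"): "in",
        ("in", "between"): "in",
        ("in", "above_end"): "out",
    }
    state = "out"
    flags = []
    for d in distances:
        if d < r_start:
            symbol = "below_start"
        elif d > r_end:
            symbol = "above_end"
        else:
            symbol = "between"
        state = transitions[(state, symbol)]
        flags.append(state == "in")
    return np.array(flags, dtype=bool)


def pearson_oracle(x, y) -> float:
    """Textbook covariance / (sigma_x sigma_y), population form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    cov = sum((xi - x.mean()) * (yi - y.mean()) for xi, yi in zip(x, y)) / n
    sx = np.sqrt(sum((xi - x.mean()) ** 2 for xi in x) / n)
    sy = np.sqrt(sum((yi - y.mean()) ** 2 for yi in y) / n)
    if sx == 0 or sy == 0:
        return 0.0
    return float(cov / (sx * sy))


def flood_fill_clusters(
    values: np.ndarray,
) -> List[Tuple[int, Set[Tuple[int, int]]]]:
    """(sign, pixel set) components of the strict upper triangle,
    8-connected, via iterative flood fill on 0-based (row, col) pixels."""
    n = values.shape[0]
    seen: Set[Tuple[int, int]] = set()
    out = []
    for r0 in range(n):
        for c0 in range(r0 + 1, n):
            if (r0, c0) in seen or values[r0, c0] == 0:
                continue
            sign = 1 if values[r0, c0] > 0 else -1
            stack = [(r0, c0)]
            comp: Set[Tuple[int, int]] = set()
            while stack:
                r, c = stack.pop()
                if (r, c) in comp:
                    continue
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < n
                            and rr < cc < n
                            and (rr, cc) not in comp
                            and np.sign(values[rr, cc]) == sign
                        ):
                            stack.append((rr, cc))
            seen |= comp
            out.append((sign, comp))
    return out


def torsion_arccos_oracle(p0, p1, p2, p3) -> float:
    """Torsion in degrees via arccos of plane normals, signed by the
    scalar triple product; cis = 0, trans = 180."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    if np.isclose(ang, -180.0):
        ang = 180.0
    return float(ang)


def groupby_oracle(rows) -> Dict[tuple, float]:
    """Mean fluorescence per (construct, conc, bio rep), dict-based."""
    sums: Dict[tuple, list] = {}
    for row in rows:
        key = (row["construct"], row["maltose_mM"], row["biological_rep"])
        sums.setdefault(key, []).append(row["fluorescence"])
    return {k: sum(v) / len(v) for k, v in sums.items()}


def two_pass_sd(values) -> float:
    """Sample standard deviation by the explicit two-pass formula."""
    values = list(values)
    mean = sum(values) / len(values)
    return (sum((v - mean) ** 2 for v in values) / (len(values) - 1)) ** 0.5
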