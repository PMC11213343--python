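"""Plate-reader fluorescence reduction to ΔF/F0 and viability calls.

The reduction order is fixed: technical replicates are averaged per
(construct, concentration, biological replicate); the matching-
concentration mean of the empty-vector background control is
subtracted; ΔF/F0 = (F_X − F_0)/F_0 is formed against the 0 mM
condition; finally values are aggregated across biological replicates
(mean, sample SD). A construct is viable when any concentration's
|ΔF/F0| exceeds the threshold (default 0.25, the conventional bar for
a useful fluorescent sensor).

ΔF/F0 is computed per biological replicate and then averaged, which
gives honest replicate SDs; ``per_replicate=False`` instead forms the
ratio from the replicate-averaged F values (the order some published
tables use — with near-zero F_0 the two can differ noticeably).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "REQUIRED_COLUMNS",
    "SensorMetrics",
    "load_plate_csv",
    "aggregate_technical",
    "background_subtract",
    "delta_f_over_f0",
    "classify_viability",
    "summarize_biological",
    "analyze_plate",
    "metrics_table",
]

REQUIRED_COLUMNS = (
    "construct",
    "maltose_mM",
    "biological_rep",
    "technical_rep",
    "fluorescence",
)

DEFAULT_CONTROL = "pET28a"


def load_plate_csv(path) -> pd.DataFrame:
    """Read a plate CSV with the required header and validate it."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    if not np.all(np.isfinite(df["fluorescence"].to_numpy(dtype=float))):
        raise ValueError("fluorescence values must be finite")
    if (df["biological_rep"] <= 0).any() or (df["technical_rep"] <= 0).any():
        raise ValueError("replicate indices must be positive")
    return df


def aggregate_technical(assay: pd.DataFrame) -> pd.DataFrame:
    """Mean over technical replicates per (construct, conc, bio rep)."""
    if assay.empty:
        raise ValueError("empty assay table")
    out = (
        assay.groupby(["construct", "maltose_mM", "biological_rep"], sort=True)[
            "fluorescence"
        ]
        .mean()
        .reset_index()
    )
    return out


def background_subtract(
    aggregated: pd.DataFrame, control_label: str = DEFAULT_CONTROL
) -> pd.DataFrame:
    """Subtract the background control's per-concentration mean.

    The control mean is taken across its biological replicates at the
    matching maltose concentration; a concentration with no control
    rows is an error.
    """
    ctrl = aggregated[aggregated["construct"] == control_label]
    if ctrl.empty:
        raise ValueError(f"no background control rows labelled {control_label!r}")
    ctrl_mean = ctrl.groupby("maltose_mM")["fluorescence"].mean()
    out = aggregated[aggregated["construct"] != control_label].copy()
    missing = sorted(set(out["maltose_mM"]) - set(ctrl_mean.index))
    if missing:
        raise ValueError(
            f"background control {control_label!r} missing for maltose "
            f"concentration(s) {missing}"
        )
    out["fluorescence"] = out["fluorescence"] - out["maltose_mM"].map(ctrl_mean)
    return out


def delta_f_over_f0(f_0: float, f_x: float) -> float:
    """(F_X − F_0)/F_0, sign preserved; NaN (with a warning) at F_0 = 0,
    where the ratio is undefined and near-zero F_0 inflates it."""
    if f_0 == 0:
        warnings.warn("F_0 is zero; ΔF/F0 undefined", stacklevel=2)
        return float("nan")
    return (f_x - f_0) / f_0


def classify_viability(dff0_values, threshold: float = 0.25) -> bool:
    """Viable iff any concentration's |ΔF/F0| exceeds the threshold."""
    vals = np.asarray(list(dff0_values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one ΔF/F0 value")
    finite = vals[np.isfinite(vals)]
    return bool(finite.size and np.max(np.abs(finite)) > threshold)


def summarize_biological(values) -> tuple:
    """(mean, sample SD) across biological replicates; SD is None for a
    single replicate."""
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), None
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else None
    return mean, sd


@dataclass
class SensorMetrics:
    """Reduced readout for one construct."""

    construct: str
    f0_mean: float  # background-subtracted mean F at 0 mM
    per_concentration: Dict[float, dict]  # conc -> {per_rep, mean, sd}
    viable: bool

    def dff0_means(self) -> Dict[float, float]:
        return {c: d["mean"] for c, d in self.per_concentration.items()}


def analyze_plate(
    assay: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    control_label: str = DEFAULT_CONTROL,
    per_replicate: bool = True,
) -> List[SensorMetrics]:
    """Full reduction: technical mean → background subtraction → ΔF/F0
    → biological aggregation → viability call."""
    config = config or AnalysisConfig()
    agg = aggregate_technical(assay)
    corrected = background_subtract(agg, control_label)
    results: List[SensorMetrics] = []
    for construct, sub in corrected.groupby("construct", sort=True):
        zero = sub[sub["maltose_mM"] == 0]
        if zero.empty:
            raise ValueError(f"{construct}: no 0 mM (F_0) condition")
        f0_by_rep = zero.set_index("biological_rep")["fluorescence"]
        concs = sorted(c for c in sub["maltose_mM"].unique() if c != 0)
        per_conc: Dict[float, dict] = {}
        for conc in concs:
            rows = sub[sub["maltose_mM"] == conc]
            if per_replicate:
                per_rep = {}
                for _, row in rows.iterrows():
                    rep = row["biological_rep"]
                    if rep not in f0_by_rep.index:
                        raise ValueError(
                            f"{construct}: biological rep {rep} lacks a 0 mM reading"
                        )
                    per_rep[int(rep)] = delta_f_over_f0(
                        f0_by_rep.loc[rep], row["fluorescence"]
                    )
                mean, sd = summarize_biological(per_rep.values())
            else:
                ratio = delta_f_over_f0(
                    float(f0_by_rep.mean()), float(rows["fluorescence"].mean())
                )
                per_rep = {}
                mean, sd = ratio, None
            per_conc[float(conc)] = {"per_rep": per_rep, "mean": mean, "sd": sd}
        dff0 = [d["mean"] for d in per_conc.values()]
        results.append(
            SensorMetrics(
                construct=str(construct),
                f0_mean=float(f0_by_rep.mean()),
                per_concentration=per_conc,
                viable=classify_viability(dff0, config.viability_threshold)
                if dff0
                else False,
            )
        )
    return results


def metrics_table(metrics: List[SensorMetrics]) -> pd.DataFrame:
    """Long-format summary table (one row per construct/concentration)."""
    rows = []
    for m in metrics:
        for conc, d in m.per_concentration.items():
            rows.append(
                {
                    "construct": m.construct,
                    "maltose_mM": conc,
                    "dff0_mean": d["mean"],
                    "dff0_sd": d["sd"] if d["sd"] is not None else np.nan,
                    "f0_mean": m.f0_mean,
                    "viable": m.viable,
                }
            )
    return pd.DataFrame(rows)
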