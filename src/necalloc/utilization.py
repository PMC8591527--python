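"""Enzyme utilization: predicted minimal vs measured abundance.

U_E[%] = [E]_minimal / [E]_measured * 100, where the minimal abundance is the
min-total-enzyme RBA solution at the condition's growth rate and the measured
abundance comes from the proteome.  Enzymes are grouped into low (<= t_low),
moderate (t_low < U <= t_high) and high (> t_high) utilization by their mean
across the designated conditions; cross-condition variability is the
coefficient of variation of measured abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

T_LOW = 33.0  # percent, boundary inclusive for "low"
T_HIGH = 66.0  # percent, boundary inclusive for "moderate"


def compute_utilization(
    predicted_min: dict[str, float] | pd.Series,
    measured: dict[str, float] | pd.Series,
    condition: str | None = None,
) -> pd.DataFrame:
    """Per-enzyme utilization for one condition.

    Enzymes measured but absent from (or zero in) the predictions get U_E = 0;
    enzymes predicted but unmeasured are retained with NaN utilization and an
    ``unmeasured`` flag; measured = 0 with predicted > 0 is flagged
    ``undefined`` rather than reported as infinity.
    """
    pred = pd.Series(dict(predicted_min), dtype=float)
    meas = pd.Series(dict(measured), dtype=float)
    ids = sorted(set(pred.index) | set(meas.index))
    rows = []
    for eid in ids:
        p = float(pred.get(eid, 0.0))
        m = meas.get(eid, np.nan)
        flag = ""
        if pd.isna(m):
            if p <= 0:
                continue  # neither predicted nor measured
            u = np.nan
            flag = "unmeasured"
        elif m == 0:
            if p > 0:
                u = np.nan
                flag = "undefined"
            else:
                u = 0.0
        else:
            u = p / m * 100.0
            if u > 100.0:
                flag = "over_unity"
        rows.append({"enzyme": eid, "condition": condition, "predicted": p,
                     "measured": np.nan if pd.isna(m) else float(m),
                     "utilization_pct": u, "flag": flag})
    return pd.DataFrame(rows, columns=["enzyme", "condition", "predicted",
                                       "measured", "utilization_pct", "flag"])


def utilization_table(
    predicted_by_condition: dict[str, dict],
    measured_by_condition: dict[str, dict],
) -> pd.DataFrame:
    """Long-format utilization over several conditions."""
    if set(predicted_by_condition) != set(measured_by_condition):
        raise ValueError("condition sets of predictions and measurements differ")
    frames = [
        compute_utilization(predicted_by_condition[c], measured_by_condition[c], c)
        for c in sorted(predicted_by_condition)
    ]
    return pd.concat(frames, ignore_index=True)


def categorize_utilization(
    records: pd.DataFrame, t_low: float = T_LOW, t_high: float = T_HIGH
) -> pd.DataFrame:
    """Mean utilization per enzyme over conditions, with category.

    Boundary convention: low if mean <= t_low, moderate if t_low < mean <=
    t_high, high above.  Over-unity means (measured below prediction) stay
    "high" and keep an over_unity flag -- a calibration diagnostic.
    """
    usable = records.dropna(subset=["utilization_pct"])
    mean = usable.groupby("enzyme")["utilization_pct"].mean()

    def category(u: float) -> str:
        if u <= t_low:
            return "low"
        if u <= t_high:
            return "moderate"
        return "high"

    out = mean.rename("mean_utilization_pct").reset_index()
    out["category"] = out["mean_utilization_pct"].map(category)
    out["over_unity"] = out["mean_utilization_pct"] > 100.0
    return out


def abundance_variability(measured_by_condition: dict[str, dict]) -> pd.Series:
    """Coefficient of variation (sample SD / mean) of per-condition mean
    abundance, per enzyme.  Requires >= 2 conditions; zero-mean enzymes get NaN."""
    if len(measured_by_condition) < 2:
        raise ValueError("abundance variability needs >= 2 conditions")
    df = pd.DataFrame({c: pd.Series(dict(v), dtype=float)
                       for c, v in measured_by_condition.items()})
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    cv = sd / mean.where(mean != 0)
    cv.name = "cv"
    return cv


def machinery_utilization(
    predicted: dict[str, float], measured: dict[str, float]
) -> pd.DataFrame:
    """Same ratio applied to machinery concentrations (e.g. ribosome reserve)."""
    return compute_utilization(predicted, measured)
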