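"""Regression metrics and structure-activity correlation tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedCorrelationError


@dataclass(frozen=True)
class MetricsReport:
    """MAE/RMSE in kJ/mol plus both r^2 conventions and residuals."""

    mae: float
    rmse: float
    r2: float          # squared Pearson correlation
    r2_ss: float       # 1 - SS_res / SS_tot
    n: int
    residuals: pd.DataFrame


def pearson_r(x, y) -> float:
    """Product-moment correlation; undefined for zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs differ in length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the inputs")
    return float(stats.pearsonr(x, y).statistic)


def regression_metrics(
    predicted, experimental, identifiers=None
) -> MetricsReport:
    """MAE, RMSE and coefficient of determination for paired predictions."""
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError("predicted and experimental differ in length")
    if pred.size < 2:
        raise ValueError(f"need at least 2 pairs, got {pred.size}")
    err = pred - exp
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    if np.ptp(pred) == 0 or np.ptp(exp) == 0:
        r2 = float("nan")
    else:
        r2 = float(stats.pearsonr(pred, exp).statistic ** 2)
    ss_tot = float(np.sum((exp - exp.mean()) ** 2))
    r2_ss = 1.0 - float(np.sum(err ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    ids = list(identifiers) if identifiers is not None else list(range(pred.size))
    residuals = pd.DataFrame(
        {"id": ids, "predicted": pred, "experimental": exp, "error": err}
    )
    return MetricsReport(mae=mae, rmse=rmse, r2=r2, r2_ss=r2_ss, n=pred.size, residuals=residuals)


def sar_correlate(
    activities: dict[str, float], strengths: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Correlate activities (id -> pIC50) against per-feature strength columns.

    Returns one row per feature with the Pearson r over the id
    intersection; a zero-variance feature is reported with ``error`` set
    and NaN r, leaving the other features unaffected.
    """
    shared = sorted(set(activities) & set(strengths))
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared identifiers, got {len(shared)}"
        )
    missing = sorted((set(activities) | set(strengths)) - set(shared))
    features: list[str] = sorted({f for i in shared for f in strengths[i]})
    act = np.array([activities[i] for i in shared], dtype=float)
    rows = []
    for feat in features:
        vals = np.array([strengths[i].get(feat, np.nan) for i in shared], dtype=float)
        ok = ~np.isnan(vals)
        try:
            r = pearson_r(act[ok], vals[ok])
            rows.append({"feature": feat, "r": r, "n": int(ok.sum()), "error": ""})
        except UndefinedCorrelationError as exc:
            rows.append({"feature": feat, "r": np.nan, "n": int(ok.sum()), "error": str(exc)})
    frame = pd.DataFrame(rows)
    frame.attrs["missing_ids"] = missing
    return frame
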