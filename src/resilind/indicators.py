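"""Resilience indicator traits from lactation-deviation series.

Three indicators are computed per cow-lactation over the retained days of
the 10-305 window:

* ``v_d`` — variance of deviations between observed and predicted daily
  yield (kg^2); small for smooth lactation curves.
* ``v_r`` — variance of relative daily yields, where yields are scaled by
  ``alpha = 100 / sum(y)`` so they sum to 100; removes the production-level
  dependence of ``v_d``.
* ``r_auto`` — lag-1 autocorrelation of the deviations (numerator divisor
  ``n - 2``, denominator divisor ``n - 1``); near 0 for cows that recover
  quickly from disturbances.

``v_d`` and ``v_r`` are log-transformed for genetic analysis (and negated
on the selection-index path so that higher values mean more resilient);
``r_auto`` enters untransformed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from resilind.config import SI_WEIGHT_VD, SI_WEIGHT_VR


class IndicatorError(ValueError):
    """Raised when an indicator is undefined for the given series."""


def variance_deviations(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Variance (divisor n-1) of the mean-centered deviations y - yhat."""
    dev = np.asarray(observed, dtype=float) - np.asarray(predicted, dtype=float)
    if dev.size < 2:
        raise IndicatorError(f"v_d needs at least 2 days, got {dev.size}")
    return float(np.var(dev, ddof=1))


def variance_relative(observed: np.ndarray) -> float:
    """Variance of relative yields alpha*y with alpha = 100 / sum(y)."""
    y = np.asarray(observed, dtype=float)
    if y.size < 2:
        raise IndicatorError(f"v_r needs at least 2 days, got {y.size}")
    total = y.sum()
    if total <= 0:
        raise IndicatorError("v_r undefined: total yield is not positive")
    return float(np.var(100.0 / total * y, ddof=1))


def autocorrelation_deviations(
    observed: np.ndarray, predicted: np.ndarray, days: np.ndarray | None = None
) -> float:
    """Lag-1 autocorrelation of deviations over consecutive retained days.

    Only pairs of deviations on consecutive calendar days are used in the
    numerator (pairs broken by removed days are skipped); the numerator sum
    is divided by ``n_pairs - 1`` and the denominator variance by
    ``n - 1``.  Returns NaN when the deviation variance is zero (flagged
    missing downstream).
    """
    dev = np.asarray(observed, dtype=float) - np.asarray(predicted, dtype=float)
    n = dev.size
    if n < 3:
        raise IndicatorError(f"r_auto needs at least 3 days, got {n}")
    dc = dev - dev.mean()
    if days is None:
        pair = np.ones(n - 1, dtype=bool)
    else:
        pair = np.diff(np.asarray(days)) == 1
    n_pairs = int(pair.sum())
    if n_pairs < 2:
        raise IndicatorError("r_auto needs at least 2 consecutive-day pairs")
    den = float(np.sum(dc * dc)) / (n - 1)
    if den == 0.0:
        return float("nan")
    num = float(np.sum(dc[1:][pair] * dc[:-1][pair])) / (n_pairs - 1)
    return num / den


def compute_indicators(series: pd.DataFrame) -> pd.DataFrame:
    """Per cow-lactation indicator table from a long-format series.

    ``series`` needs columns ``animal_id, lactation, day_in_milk, observed,
    predicted``.  Output columns: ``vd, vr, rauto, alpha, n`` plus a
    ``flag`` column marking degenerate records (zero deviation variance).
    """
    rows = []
    for (animal, lact), grp in series.groupby(["animal_id", "lactation"], sort=True):
        obs = grp["observed"].to_numpy()
        pred = grp["predicted"].to_numpy()
        days = grp["day_in_milk"].to_numpy()
        vd = variance_deviations(obs, pred)
        vr = variance_relative(obs)
        if vd == 0.0:
            rauto, flag = float("nan"), "zero_deviation_variance"
        else:
            rauto = autocorrelation_deviations(obs, pred, days)
            flag = ""
        rows.append({
            "animal_id": animal, "lactation": int(lact), "vd": vd, "vr": vr,
            "rauto": rauto, "alpha": 100.0 / obs.sum(), "n": obs.size, "flag": flag,
        })
    return pd.DataFrame(rows)


def transform_indicators(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-transform the variance indicators for genetic analysis.

    Adds ``ln_vd, ln_vr`` (analysis scale) and ``neg_ln_vd, neg_ln_vr``
    (selection-index scale: higher = more resilient); ``rauto`` passes
    through.  Records with non-positive variances are excluded and
    returned in the audit frame.
    """
    ok = (records["vd"] > 0) & (records["vr"] > 0)
    excluded = records.loc[~ok].assign(reason="non_positive_variance")
    out = records.loc[ok].copy()
    out["ln_vd"] = np.log(out["vd"])
    out["ln_vr"] = np.log(out["vr"])
    out["neg_ln_vd"] = -out["ln_vd"]
    out["neg_ln_vr"] = -out["ln_vr"]
    return out.reset_index(drop=True), excluded.reset_index(drop=True)


def selection_index(
    gebv_vd: np.ndarray | pd.Series,
    gebv_vr: np.ndarray | pd.Series,
    weights: tuple[float, float] = (SI_WEIGHT_VD, SI_WEIGHT_VR),
) -> np.ndarray:
    """Resilience selection index from standardized GEBVs.

    ``SI = 0.65 * gebv_vd + 0.35 * gebv_vr`` with the default weights,
    where the inputs are GEBVs of the negated log variance indicators.
    Records with a missing component yield NaN (skipped downstream).
    """
    w_vd, w_vr = weights
    return w_vd * np.asarray(gebv_vd, dtype=float) + w_vr * np.asarray(gebv_vr, dtype=float)
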