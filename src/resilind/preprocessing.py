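"""From milking events to filtered daily-yield lactation series.

The processing chain is: (1) aggregate milking events into daily yields,
splitting each day's first milking proportionally between the current and
the previous day; (2) remove farm-days whose milked-animal count deviates
by >= 3 SD from the farm's mean count, together with the adjacent days;
(3) remove the day before and after every individual data gap of an animal;
(4) window each lactation to days 10-305 and keep it only with >= 148
retained days (50% coverage of the 296-day window); (5) fit a penalized
spline (5 effective degrees of freedom) per lactation with iterative
down-weighting of assumed disturbance days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import brentq

log = logging.getLogger(__name__)

#: lactation window (days in milk, calving day = day 0), inclusive
WINDOW = (10, 305)
#: minimum retained days for a lactation (50% of the 296 possible days)
MIN_COVERAGE_DAYS = 148
#: farm-day count filter threshold, in SDs (inclusive)
FARM_SD_THRESHOLD = 3.0


class InputError(ValueError):
    """Raised on malformed milking-record input."""


@dataclass
class FilterAudit:
    """Counts of records/days removed per rule, reconciling in- and output."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, rule: str, removed: int) -> None:
        self.counts[rule] = self.counts.get(rule, 0) + int(removed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.counts), "removed": list(self.counts.values())}
        )


def aggregate_daily_yields(records: pd.DataFrame) -> pd.DataFrame:
    """Sum milking yields into daily yields per animal.

    The first milking of each calendar day is divided between the previous
    and the current day, proportional to the fraction of its inter-milking
    interval that falls on each day; all other milkings count wholly toward
    their own day.  The first recorded milking of an animal (no
    predecessor) is wholly assigned to its own day.

    Parameters
    ----------
    records
        Columns ``animal_id, farm_id, timestamp, yield_kg``; timestamps
        must be strictly increasing per animal and yields non-negative.

    Returns
    -------
    DataFrame with columns ``animal_id, farm_id, date, yield_kg,
    n_milkings`` (one row per animal-day; same-day contributions are
    summed, conserving total milk mass).  ``n_milkings`` counts the
    milking events recorded on the day itself: a day that only receives
    spill-over from the next day's first milking has ``n_milkings == 0``
    and counts as a day without available data for the gap filter.
    """
    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    if (rec["yield_kg"] < 0).any():
        bad = rec.loc[rec["yield_kg"] < 0].iloc[0]
        raise InputError(f"negative milking yield for animal {bad['animal_id']}")
    rec = rec.sort_values(["animal_id", "timestamp"], kind="mergesort")
    if rec.groupby("animal_id")["timestamp"].diff().le(pd.Timedelta(0)).any():
        raise InputError("milking timestamps not strictly increasing within animal")

    ts = rec["timestamp"]
    day = ts.dt.normalize()
    prev_ts = rec.groupby("animal_id")["timestamp"].shift()
    first_of_day = day.ne(prev_ts.dt.normalize())

    # fraction of the inter-milking interval on the current day
    interval = (ts - prev_ts).dt.total_seconds()
    since_midnight = (ts - day).dt.total_seconds()
    frac_current = np.minimum(since_midnight / interval.replace(0, np.nan), 1.0)
    split = first_of_day & prev_ts.notna()
    frac_current = np.where(split, frac_current, 1.0)
    frac_current = np.nan_to_num(frac_current, nan=1.0)

    current = pd.DataFrame({
        "animal_id": rec["animal_id"],
        "farm_id": rec["farm_id"],
        "date": day,
        "yield_kg": rec["yield_kg"] * frac_current,
        "n_milkings": 1,
    })
    spill_mask = split & (frac_current < 1.0)
    spill = rec.loc[spill_mask]
    previous = pd.DataFrame({
        "animal_id": spill["animal_id"],
        "farm_id": spill["farm_id"],
        "date": day.loc[spill.index] - pd.Timedelta(days=1),
        "yield_kg": spill["yield_kg"] * (1.0 - frac_current[spill_mask]),
        "n_milkings": 0,
    })
    daily = (
        pd.concat([current, previous], ignore_index=True)
        .groupby(["animal_id", "farm_id", "date"], as_index=False)
        .agg(yield_kg=("yield_kg", "sum"), n_milkings=("n_milkings", "sum"))
    )
    return daily.sort_values(["animal_id", "date"]).reset_index(drop=True)


def filter_farm_days(daily: pd.DataFrame, audit: FilterAudit | None = None,
                     sd_threshold: float = FARM_SD_THRESHOLD) -> pd.DataFrame:
    """Drop abnormal farm-days (and their neighbours) for all of a farm's animals.

    A farm-day is abnormal when its milked-animal count deviates by at
    least ``sd_threshold`` standard deviations from the farm's mean daily
    count (SD over all of the farm's days in the data).  Farms with fewer
    than two days of data are skipped with a warning.
    """
    counts = daily.groupby(["farm_id", "date"])["animal_id"].nunique().rename("n")
    stats_ = counts.groupby("farm_id").agg(["mean", "std", "count"])
    drop_keys: set[tuple] = set()
    for farm, row in stats_.iterrows():
        if row["count"] < 2:
            log.warning("farm %s has < 2 days of data; count filter skipped", farm)
            continue
        if not np.isfinite(row["std"]) or row["std"] == 0:
            continue
        farm_counts = counts.loc[farm]
        dev = (farm_counts - row["mean"]).abs() / row["std"]
        for d in farm_counts.index[dev >= sd_threshold]:
            for off in (-1, 0, 1):
                drop_keys.add((farm, d + pd.Timedelta(days=off)))
    if not drop_keys:
        if audit is not None:
            audit.add("farm_day_filter", 0)
        return daily
    key = pd.MultiIndex.from_frame(daily[["farm_id", "date"]])
    mask = key.isin(drop_keys)
    if audit is not None:
        audit.add("farm_day_filter", int(mask.sum()))
    return daily.loc[~mask].reset_index(drop=True)


def remove_gap_adjacent_days(days: np.ndarray, observed: np.ndarray | None = None) -> np.ndarray:
    """Return the subset of ``days`` kept after removing gap-adjacent days.

    ``days`` is a sorted integer day sequence of one animal's lactation.
    A gap is a maximal run of days *without data* inside the observed
    range; the present day immediately before and after each gap is
    removed.  ``observed`` names the days that actually carry data (it
    defaults to ``days``): days removed by this filter itself do not count
    as new gaps, which makes the filter idempotent given a fixed
    ``observed`` reference.
    """
    days = np.asarray(days)
    obs = days if observed is None else np.asarray(observed)
    if obs.size <= 1:
        return days
    jump = np.diff(obs) > 1
    drop_days = set(obs[:-1][jump]) | set(obs[1:][jump])
    return days[~np.isin(days, list(drop_days))]


def _apply_gap_filter(daily: pd.DataFrame, audit: FilterAudit | None) -> pd.DataFrame:
    def keep_days(group: pd.DataFrame) -> pd.DataFrame:
        kept = remove_gap_adjacent_days(group["day_in_milk"].to_numpy())
        return group[group["day_in_milk"].isin(kept)]

    before = len(daily)
    out = (
        daily.sort_values(["animal_id", "lactation", "day_in_milk"])
        .groupby(["animal_id", "lactation"], group_keys=False)[daily.columns]
        .apply(keep_days)
        .reset_index(drop=True)
    )
    if audit is not None:
        audit.add("gap_adjacent_filter", before - len(out))
    return out


def window_and_coverage_filter(
    daily: pd.DataFrame, audit: FilterAudit | None = None,
    window: tuple[int, int] = WINDOW, min_days: int = MIN_COVERAGE_DAYS,
) -> pd.DataFrame:
    """Keep days 10-305 and lactations with at least 148 retained days."""
    lo, hi = window
    in_window = daily["day_in_milk"].between(lo, hi)
    if audit is not None:
        audit.add("window_filter", int((~in_window).sum()))
    windowed = daily.loc[in_window]
    n_days = windowed.groupby(["animal_id", "lactation"])["day_in_milk"].transform("size")
    retained = n_days >= min_days
    if audit is not None:
        audit.add("coverage_filter", int((~retained).sum()))
    return windowed.loc[retained].reset_index(drop=True)


def _bspline_design(x: np.ndarray, n_basis: int, degree: int = 3) -> tuple[np.ndarray, BSpline]:
    """Cubic B-spline design on equally spaced knots extended past the data.

    Uniform (unclamped) knots keep the difference penalty's null space equal
    to polynomials: the B-spline coefficients of any cubic lie on a cubic at
    the equally spaced Greville points, so fourth differences vanish.
    """
    lo, hi = float(x.min()), float(x.max())
    n_seg = n_basis - degree
    h = (hi - lo) / n_seg
    knots = lo + h * np.arange(-degree, n_seg + degree + 1)
    spl = BSpline(knots, np.eye(n_basis), degree, extrapolate=True)
    return spl(x), spl


def fit_lactation_curve(
    days: np.ndarray,
    yields: np.ndarray,
    df: float = 5.0,
    n_basis: int = 24,
    n_reweight: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Penalized-spline prediction of the undisturbed lactation curve.

    A cubic B-spline basis with a fourth-order difference penalty is fitted
    by penalized weighted least squares; the penalty weight is chosen so
    the effective degrees of freedom (trace of the hat matrix) equal
    ``df``.  Because the penalty null space contains all cubics, an exact
    cubic polynomial is reproduced without bias at any penalty strength.

    Disturbance down-weighting: after each fit, days with negative
    residuals are down-weighted proportionally to the residual magnitude
    (weights clipped to [0.1, 1]) and the curve is refitted — a pluggable
    stand-in for weighting by "assumed disturbance strength", so that
    yield drops pull the predicted curve down as little as possible.

    Returns ``(predicted, weights)`` over the input days.
    """
    days = np.asarray(days, dtype=float)
    yields = np.asarray(yields, dtype=float)
    n = days.size
    if n <= n_basis:
        raise ValueError(f"need more than {n_basis} points for the spline fit, got {n}")
    if not 4.0 < df < n_basis:
        raise ValueError(f"df must lie in (4, {n_basis}), got {df}")
    B, _ = _bspline_design(days, n_basis)
    D = np.diff(np.eye(n_basis), n=4, axis=0)
    P = D.T @ D

    def fit_once(w: np.ndarray) -> tuple[np.ndarray, float]:
        BtW = B.T * w
        BtWB = BtW @ B

        def edf(log_lam: float) -> float:
            H = np.linalg.solve(BtWB + np.exp(log_lam) * P, BtWB)
            return float(np.trace(H))

        lo_l, hi_l = -10.0, 25.0
        if edf(lo_l) < df:  # basis smaller than requested df: no penalty needed
            lam = np.exp(lo_l)
        else:
            lam = np.exp(brentq(lambda t: edf(t) - df, lo_l, hi_l, xtol=1e-3))
        coef = np.linalg.solve(BtWB + lam * P, BtW @ yields)
        return B @ coef, lam

    w = np.ones(n)
    pred, _ = fit_once(w)
    for _ in range(n_reweight):
        resid = yields - pred
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        scale = max(scale, 1e-8)
        w = np.where(resid < 0, np.clip(1.0 - np.abs(resid) / (3.0 * scale), 0.1, 1.0), 1.0)
        pred, _ = fit_once(w)
    return pred, w


def assign_lactations(daily: pd.DataFrame, calvings: pd.DataFrame) -> pd.DataFrame:
    """Attach lactation number and day in milk (calving day = day 0)."""
    cal = calvings[["animal_id", "lactation", "calving_date"]].copy()
    cal["calving_date"] = pd.to_datetime(cal["calving_date"])
    cal = cal.sort_values("calving_date", kind="mergesort")
    d = daily.sort_values("date", kind="mergesort")
    merged = pd.merge_asof(
        d, cal, by="animal_id", left_on="date", right_on="calving_date",
        direction="backward",
    )
    merged = merged.dropna(subset=["lactation"])
    merged["lactation"] = merged["lactation"].astype(int)
    merged["day_in_milk"] = (merged["date"] - merged["calving_date"]).dt.days
    return merged.sort_values(["animal_id", "lactation", "day_in_milk"]).reset_index(drop=True)


def build_lactation_series(
    milkings: pd.DataFrame,
    calvings: pd.DataFrame,
    spline_df: float = 5.0,
) -> tuple[pd.DataFrame, FilterAudit]:
    """Full preprocessing chain: events -> filtered series with fitted curve.

    Returns a long-format table (``animal_id, lactation, day_in_milk,
    observed, predicted, weight``) for every retained lactation, plus the
    filter audit.
    """
    audit = FilterAudit()
    daily = aggregate_daily_yields(milkings)
    audit.add("input_days", -len(daily))  # negative: counts entering, for reconciliation
    # days with no recorded milking (spill-over only) are "no data" days
    spill_only = daily["n_milkings"] == 0
    audit.add("no_milking_days", int(spill_only.sum()))
    daily = daily.loc[~spill_only].reset_index(drop=True)
    daily = filter_farm_days(daily, audit)
    daily = assign_lactations(daily, calvings)
    daily = _apply_gap_filter(daily, audit)
    daily = window_and_coverage_filter(daily, audit)

    out = []
    for (animal, lact), grp in daily.groupby(["animal_id", "lactation"], sort=True):
        days = grp["day_in_milk"].to_numpy()
        obs = grp["yield_kg"].to_numpy()
        pred, w = fit_lactation_curve(days, obs, df=spline_df)
        out.append(pd.DataFrame({
            "animal_id": animal, "lactation": lact, "day_in_milk": days,
            "observed": obs, "predicted": pred, "weight": w,
        }))
    series = (pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["animal_id", "lactation", "day_in_milk", "observed", "predicted", "weight"]))
    return series, audit
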