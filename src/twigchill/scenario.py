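"""Budburst warming-scenario simulator.

Builds on the fitted logarithmic critical-forcing model
GDDcrit = a + b*ln(CD): given a base year of daily mean temperatures, apply
winter and/or spring warming offsets, accumulate chill days (CD, daily mean
below the CD threshold) and growing degree-days (GDD, excess of the daily
mean over the GDD threshold) in parallel from an accumulation start date,
and predict budburst as the first day whose accumulated GDD meets the
critical forcing implied by the chilling accumulated so far.

Winter warming can *delay* budburst when the critical-forcing curve is
steeply decreasing in chilling: warming removes chill days, raising GDDcrit
faster than the extra warmth accumulates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import LogFit

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "apply_warming",
    "accumulate_cd_gdd",
    "predict_budburst",
    "scenario_sweep",
]

#: Warming offsets considered by the simulator, degrees C.
OFFSET_RANGE: tuple[float, float] = (-1.0, 5.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """One warming scenario: offsets, season windows and thresholds.

    Windows are inclusive date ranges.  Defaults follow meteorological
    seasons (winter Dec-Feb, spring Mar-May) with accumulation starting
    1 November of the base winter.
    """

    dt_winter: float = 0.0
    dt_spring: float = 0.0
    winter_window: tuple[dt.date, dt.date] = (dt.date(2015, 12, 1), dt.date(2016, 2, 29))
    spring_window: tuple[dt.date, dt.date] = (dt.date(2016, 3, 1), dt.date(2016, 5, 31))
    accumulation_start: dt.date = dt.date(2015, 11, 1)
    cd_threshold: float = 5.0
    gdd_threshold: float = 5.0
    offset_range: tuple[float, float] = OFFSET_RANGE

    def __post_init__(self) -> None:
        lo, hi = self.offset_range
        for name, v in (("dt_winter", self.dt_winter), ("dt_spring", self.dt_spring)):
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside configured range [{lo}, {hi}]")
        (w0, w1), (s0, s1) = self.winter_window, self.spring_window
        if w1 < w0 or s1 < s0:
            raise ValueError("window end before start")
        if w0 <= s1 and s0 <= w1:
            raise ValueError("winter and spring windows overlap")


@dataclass
class ScenarioResult:
    """Predicted budburst for one scenario, with the full trajectory."""

    spec: ScenarioSpec
    budburst_date: Optional[dt.date]
    cd_at_budburst: float
    gdd_at_budburst: float
    trajectory: pd.DataFrame  # date-indexed: tmean, cd, gdd, gdd_crit

    @property
    def budburst_doy_offset(self) -> Optional[int]:
        if self.budburst_date is None:
            return None
        return (self.budburst_date - self.spec.accumulation_start).days


def _check_daily(daily: pd.DataFrame) -> pd.DataFrame:
    if "tmean" not in daily.columns:
        raise ValueError("daily summary needs a 'tmean' column")
    return daily


def apply_warming(daily: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Shift daily means by the scenario offsets inside their windows."""
    daily = _check_daily(daily)
    dates = np.asarray(daily.index)
    out = daily.copy()
    for (d0, d1), offset in ((spec.winter_window, spec.dt_winter),
                             (spec.spring_window, spec.dt_spring)):
        mask = (dates >= d0) & (dates <= d1)
        if offset != 0.0 and not mask.any():
            raise ValueError(
                f"warming window {d0} .. {d1} has no overlap with the daily series"
            )
        out.loc[mask, "tmean"] += offset
    return out


def accumulate_cd_gdd(
    daily: pd.DataFrame,
    start: dt.date,
    cd_threshold: float = 5.0,
    gdd_threshold: float = 5.0,
) -> pd.DataFrame:
    """Parallel cumulative chill-day and degree-day trajectories from ``start``.

    CD(t) counts days in [start, t] with mean below the CD threshold; GDD(t)
    sums the excess over the GDD threshold on days at or above it.
    """
    daily = _check_daily(daily)
    if start not in daily.index:
        raise ValueError(f"start {start} outside daily span")
    sub = daily.loc[np.asarray(daily.index) >= start]
    t = sub["tmean"].to_numpy(dtype=float)
    cd = np.cumsum(t < cd_threshold).astype(float)
    gdd = np.cumsum(np.where(t >= gdd_threshold, t - gdd_threshold, 0.0))
    out = pd.DataFrame({"tmean": t, "cd": cd, "gdd": gdd}, index=sub.index)
    out.index.name = "date"
    return out


def predict_budburst(
    daily: pd.DataFrame, fit: LogFit, spec: ScenarioSpec
) -> ScenarioResult:
    """First day on which accumulated GDD meets GDDcrit(CD so far).

    The criterion requires CD >= 1 (ln of zero chilling is undefined — the
    model has no prediction before any chilling at all has accrued).
    Returns ``budburst_date=None`` if the condition is never met in span.
    """
    import warnings

    warmed = apply_warming(daily, spec)
    traj = accumulate_cd_gdd(warmed, spec.accumulation_start,
                             spec.cd_threshold, spec.gdd_threshold)
    if len(traj) < 30:
        warnings.warn("base-year span shorter than 30 days; prediction unreliable")
    cd = traj["cd"].to_numpy()
    gdd = traj["gdd"].to_numpy()
    with np.errstate(divide="ignore"):
        crit = np.where(cd >= 1, fit.gdd_crit(np.maximum(cd, 1e-300)), np.inf)
    traj = traj.assign(gdd_crit=crit)
    hit = np.flatnonzero((cd >= 1) & (gdd >= crit))
    if len(hit) == 0:
        return ScenarioResult(spec, None, float(cd[-1]), float(gdd[-1]), traj)
    k = int(hit[0])
    date = traj.index[k]
    if isinstance(date, pd.Timestamp):
        date = date.date()
    return ScenarioResult(spec, date, float(cd[k]), float(gdd[k]), traj)


def scenario_sweep(
    daily: pd.DataFrame,
    fit: LogFit,
    dt_grid: Sequence[tuple[float, float]],
    base_spec: Optional[ScenarioSpec] = None,
) -> pd.DataFrame:
    """Predict budburst over a grid of (dt_winter, dt_spring) offsets.

    Returns a table of budburst dates and shifts (days, positive = later)
    relative to the unwarmed (0, 0) baseline of the same base year.
    """
    if len(dt_grid) == 0:
        raise ValueError("empty scenario grid")
    base_spec = base_spec or ScenarioSpec()
    import dataclasses

    baseline = predict_budburst(
        daily, fit, dataclasses.replace(base_spec, dt_winter=0.0, dt_spring=0.0)
    )
    rows = []
    for dw, ds in dt_grid:
        spec = dataclasses.replace(base_spec, dt_winter=dw, dt_spring=ds)
        res = predict_budburst(daily, fit, spec)
        shift = None
        if res.budburst_date is not None and baseline.budburst_date is not None:
            shift = (res.budburst_date - baseline.budburst_date).days
        rows.append(
            {"dt_winter": dw, "dt_spring": ds, "budburst_date": res.budburst_date,
             "shift_days": shift, "cd_at_budburst": res.cd_at_budburst,
             "gdd_at_budburst": res.gdd_at_budburst}
        )
    return pd.DataFrame(rows)
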