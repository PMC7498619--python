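"""Chilling and forcing accumulation metrics, plus linear gap imputation.

Three accumulation definitions are supported for both roles:

``subdaily``
    Sample-level accumulation from the 10-min log.  Chilling: time (in
    fractional days) spent below the threshold.  Forcing: growing
    degree-days, sum of (T - threshold) * interval over samples at or above
    the threshold.
``dailymean``
    Day-level accumulation from daily mean temperatures.  Chilling: count of
    days with mean below the threshold.  Forcing: sum of (mean - threshold)
    over days at or above it.
``calendar``
    Plain elapsed days in the window, regardless of temperature ("days
    outside" / "days inside").

Windows are half-open ``[start, end)``: the cutting moment ends chilling and
begins forcing with no double counting.  Chilling uses strict ``<`` and
forcing ``>=``, so a sample exactly at the threshold counts toward forcing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import BBCH_STAGES, TemperatureSeries, TwigRecord, stage_ordinal

__all__ = [
    "AccumulationSpec",
    "DEFAULT_SPECS",
    "daily_means",
    "impute_logger_gap",
    "impute_bbch",
    "accumulate",
]

DEFINITIONS = ("subdaily", "dailymean", "calendar")
ROLES = ("chilling", "forcing")


@dataclass(frozen=True)
class AccumulationSpec:
    """One accumulation rule: definition, temperature threshold and role."""

    definition: str
    threshold: float = 5.0
    role: str = "chilling"

    def __post_init__(self) -> None:
        if self.definition not in DEFINITIONS:
            raise ValueError(f"unknown definition {self.definition!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


#: The default 5 C chilling/forcing pairs under all three definitions.
DEFAULT_SPECS: tuple[AccumulationSpec, ...] = tuple(
    AccumulationSpec(d, 5.0, r) for d in DEFINITIONS for r in ROLES
)


def daily_means(series: TemperatureSeries) -> pd.DataFrame:
    """Arithmetic mean temperature per calendar day.

    Returns a DataFrame indexed by date with a ``tmean`` column covering
    every day in the series span; days with no valid samples are NaN.
    """
    if len(series.data) == 0:
        raise ValueError("empty temperature series")
    temps = series.temps
    by_day = temps.groupby(temps.index.date).mean()
    all_days = pd.date_range(series.data.index[0].date(),
                             series.data.index[-1].date(), freq="D").date
    out = by_day.reindex(all_days)
    out.index.name = "date"
    return out.rename("tmean").to_frame()


def impute_logger_gap(series: TemperatureSeries) -> TemperatureSeries:
    """Fill missing (NaN) samples by linear interpolation in time.

    Gaps must be interior — flanked by valid samples on both sides; no
    extrapolation is performed.  Original samples are never altered.
    """
    temps = series.temps
    if not temps.isna().any():
        return series
    if np.isnan(temps.iloc[0]) or np.isnan(temps.iloc[-1]):
        raise ValueError("gap at series boundary: cannot extrapolate")
    out = series.copy()
    t = temps.index.view("int64").astype(float)
    valid = ~temps.isna().to_numpy()
    filled = np.interp(t, t[valid], temps.to_numpy()[valid])
    out.data["temp_c"] = filled
    return out


def _round_half_down(x: float) -> int:
    """Round to nearest integer, ties toward the lower integer (2.5 -> 2)."""
    return int(np.ceil(x - 0.5))


def impute_bbch(record: TwigRecord, round_half_up: bool = False) -> TwigRecord:
    """Fill missing BBCH entries by linear interpolation on the stage ordinal.

    Interpolation runs on the position of the code in the valid stage
    sequence (0, 1, 3, 7, 9, 10, 11, 12) against observation date, then the
    result is rounded back to a valid code — half-down by default, since a
    stage is only recorded once it has clearly been reached.  Leading or
    trailing missing entries stay missing (no extrapolation).
    """
    obs = record.observations
    if all(c is not None for _, c in obs):
        return record
    dates = [d for d, _ in obs]
    x = np.array([(d - dates[0]).days for d in dates], dtype=float)
    ords = np.array(
        [stage_ordinal(c) if c is not None else np.nan for _, c in obs], dtype=float
    )
    valid = ~np.isnan(ords)
    if valid.sum() == 0:
        return record
    first, last = np.flatnonzero(valid)[[0, -1]]
    interp = np.interp(x, x[valid], ords[valid])
    rounder = (lambda v: int(np.floor(v + 0.5))) if round_half_up else _round_half_down
    new_obs = []
    for k, (d, c) in enumerate(obs):
        if c is None and first <= k <= last:
            new_obs.append((d, BBCH_STAGES[rounder(interp[k])]))
        else:
            new_obs.append((d, c))
    return TwigRecord(record.twig_id, record.treatment, record.cutting_index,
                      record.cutting_date, new_obs, record.status, record.status_date)


def _as_datetime(x) -> dt.datetime:
    if isinstance(x, dt.datetime):
        return x
    if isinstance(x, dt.date):
        return dt.datetime.combine(x, dt.time())
    return pd.Timestamp(x).to_pydatetime()


def accumulate(obj, window, spec: AccumulationSpec) -> float:
    """Accumulate chilling or forcing over a half-open window.

    Parameters
    ----------
    obj
        A :class:`TemperatureSeries` (required for ``subdaily``) or a daily
        summary DataFrame as returned by :func:`daily_means` (accepted for
        ``dailymean``; either works, series are aggregated on the fly).
        Ignored for ``calendar``.
    window
        ``(start, end)`` datetimes or dates; ``[start, end)``.
    spec
        The accumulation rule.
    """
    start, end = (_as_datetime(window[0]), _as_datetime(window[1]))
    if end < start:
        raise ValueError(f"reversed window {start} .. {end}")

    if spec.definition == "calendar":
        return (end - start).total_seconds() / 86400.0

    if spec.definition == "subdaily":
        if not isinstance(obj, TemperatureSeries):
            raise TypeError("subdaily accumulation needs a TemperatureSeries")
        if not obj.covers(start, end):
            raise ValueError(
                f"window {start} .. {end} outside series span {obj.start} .. {obj.end}"
            )
        sel = obj.temps[(obj.data.index >= start) & (obj.data.index < end)]
        vals = sel.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("window contains missing samples; impute first")
        dt_days = obj.resolution_minutes / 1440.0
        if spec.role == "chilling":
            return float(np.count_nonzero(vals < spec.threshold) * dt_days)
        above = vals[vals >= spec.threshold]
        return float(np.sum(above - spec.threshold) * dt_days)

    # dailymean
    if isinstance(obj, TemperatureSeries):
        daily = daily_means(obj)
    else:
        daily = obj
    if start.time() != dt.time() or end.time() != dt.time():
        raise ValueError("dailymean accumulation requires midnight-aligned windows")
    if start == end:
        return 0.0
    days = pd.date_range(start.date(), end.date(), freq="D", inclusive="left").date
    if len(days) == 0:
        return 0.0
    missing = [d for d in days if d not in daily.index]
    if missing:
        raise ValueError(f"window days missing from daily summary: {missing[:3]} ...")
    means = daily.loc[list(days), "tmean"].to_numpy(dtype=float)
    if np.isnan(means).any():
        raise ValueError("window contains days with no samples; impute first")
    if spec.role == "chilling":
        return float(np.count_nonzero(means < spec.threshold))
    above = means[means >= spec.threshold]
    return float(np.sum(above - spec.threshold))
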