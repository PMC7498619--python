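"""Build the analysis table: one row per twig x developmental endpoint.

Each row carries the chilling accumulated outdoors over [experiment start,
cutting date) and the forcing accumulated indoors over [cutting date, event
date), under each accumulation definition.  Endpoints are death, BBCH 7, 9,
11 and leaf out; a twig that never reaches an endpoint contributes no row
for it.  Calendar chilling + calendar forcing therefore always equals the
days from experiment start to the event date.

The table is a tidy :class:`pandas.DataFrame` with columns::

    twig_id, treatment, cutting_index, endpoint, event_date,
    chill_subdaily, chill_dailymean, chill_calendar,
    force_subdaily, force_dailymean, force_calendar, excluded
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from .metrics import AccumulationSpec, DEFAULT_SPECS, accumulate
from .types import (
    ENDPOINT_STAGES,
    LEAFOUT_STAGE,
    CuttingSchedule,
    TemperatureSeries,
    TwigRecord,
)

__all__ = [
    "final_stage",
    "event_date_for",
    "build_table",
    "filter_low_support",
    "mark_outliers",
]

log = logging.getLogger(__name__)

_ROLE_PREFIX = {"chilling": "chill", "forcing": "force"}


def final_stage(record: TwigRecord, end_date: dt.date):
    """Terminal (stage, status, date) of one twig.

    A twig ends dead (at its death date), leafed out (first visit with
    BBCH >= 12), or censored at ``end_date`` with its last recorded stage.
    """
    obs = record.observed()
    if not obs:
        raise ValueError(f"twig {record.twig_id} has no observations")
    last_stage = max(c for _, c in obs)
    if record.status == "dead":
        return last_stage, "dead", record.status_date
    for d, c in obs:
        if c >= LEAFOUT_STAGE:
            return c, "leafout", d
    return last_stage, "censored", end_date


def event_date_for(record: TwigRecord, endpoint: str) -> Optional[dt.date]:
    """First visit date at which ``endpoint`` was reached, or None.

    ``endpoint`` is ``"dead"`` (returns the death date) or one of the stage
    endpoints; ties are allowed — one visit can satisfy several endpoints.
    """
    if endpoint == "dead":
        return record.status_date if record.status == "dead" else None
    if endpoint not in ENDPOINT_STAGES:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    stage = ENDPOINT_STAGES[endpoint]
    for d, c in record.observed():
        if c >= stage:
            return d
    return None


def _value_columns(specs: Iterable[AccumulationSpec]) -> list[str]:
    return [f"{_ROLE_PREFIX[s.role]}_{s.definition}" for s in specs]


def build_table(
    records: Sequence[TwigRecord],
    outdoor: TemperatureSeries,
    indoor: TemperatureSeries,
    schedule: CuttingSchedule,
    specs: Sequence[AccumulationSpec] = DEFAULT_SPECS,
) -> pd.DataFrame:
    """Compute the per-twig, per-endpoint chilling/forcing table."""
    start = dt.datetime.combine(schedule.start_date, dt.time())
    end = dt.datetime.combine(schedule.end_date, dt.time())
    for series, name in ((outdoor, "outdoor"), (indoor, "indoor")):
        if not series.covers(start, end):
            raise ValueError(
                f"{name} series does not cover {start} .. {end} "
                f"(has {series.start} .. {series.end})"
            )
    chill_specs = [s for s in specs if s.role == "chilling"]
    force_specs = [s for s in specs if s.role == "forcing"]

    chill_cache: dict[dt.date, dict[str, float]] = {}
    force_cache: dict[tuple[dt.date, dt.date], dict[str, float]] = {}
    rows = []
    for r in records:
        cut = dt.datetime.combine(r.cutting_date, dt.time())
        if r.cutting_date not in chill_cache:
            chill_cache[r.cutting_date] = {
                f"chill_{s.definition}": accumulate(outdoor, (start, cut), s)
                for s in chill_specs
            }
        for endpoint in ("dead", "bbch7", "bbch9", "bbch11", "leafout"):
            ev = event_date_for(r, endpoint)
            if ev is None:
                continue
            key = (r.cutting_date, ev)
            if key not in force_cache:
                ev_dt = dt.datetime.combine(ev, dt.time())
                force_cache[key] = {
                    f"force_{s.definition}": accumulate(indoor, (cut, ev_dt), s)
                    for s in force_specs
                }
            rows.append(
                {
                    "twig_id": r.twig_id,
                    "treatment": r.treatment,
                    "cutting_index": r.cutting_index,
                    "endpoint": endpoint,
                    "event_date": ev,
                    **chill_cache[r.cutting_date],
                    **force_cache[key],
                    "excluded": False,
                }
            )
    columns = (
        ["twig_id", "treatment", "cutting_index", "endpoint", "event_date"]
        + [f"chill_{s.definition}" for s in chill_specs]
        + [f"force_{s.definition}" for s in force_specs]
        + ["excluded"]
    )
    return pd.DataFrame(rows, columns=columns)


def filter_low_support(
    table: pd.DataFrame,
    min_chill_days: float = 25.0,
    endpoints: Iterable[str] = ("bbch9", "bbch11"),
    min_rows: int = 3,
) -> pd.DataFrame:
    """Drop thinly supported low-chilling rows at late endpoints.

    Rows at the named endpoints with calendar chilling below
    ``min_chill_days`` are removed when fewer than ``min_rows`` rows back
    that (endpoint, cutting date) cell — late stages are rarely reached
    without chilling, and near-empty cells destabilise the fits.
    """
    if table.empty:
        return table
    endpoints = set(endpoints)
    cand = table["endpoint"].isin(endpoints) & (table["chill_calendar"] < min_chill_days)
    counts = table.groupby(["endpoint", "cutting_index"])["twig_id"].transform("size")
    drop = cand & (counts < min_rows)
    if drop.any():
        dropped = table.loc[drop, ["endpoint", "cutting_index", "twig_id"]]
        log.info("filter_low_support: removing %d rows: %s", drop.sum(),
                 dropped.to_dict("records"))
    return table.loc[~drop].reset_index(drop=True)


def mark_outliers(table: pd.DataFrame, rule: dict) -> pd.DataFrame:
    """Flag outlier rows for exclusion from fitting (rows are retained).

    ``rule`` is either ``{"ids": [twig_id or (twig_id, endpoint), ...]}`` for
    manual exclusion, or ``{"endpoint": ..., "max_forcing": ...,
    "definition": ...}`` to flag rows above a forcing ceiling at one
    endpoint (``definition`` defaults to ``"subdaily"``).
    """
    out = table.copy()
    if "ids" in rule:
        for ident in rule["ids"]:
            if isinstance(ident, tuple):
                twig, endpoint = ident
                mask = (out["twig_id"] == twig) & (out["endpoint"] == endpoint)
            else:
                mask = out["twig_id"] == ident
            if not mask.any():
                raise KeyError(f"unknown outlier id {ident!r}")
            out.loc[mask, "excluded"] = True
        return out
    if "endpoint" in rule and "max_forcing" in rule:
        col = f"force_{rule.get('definition', 'subdaily')}"
        mask = (out["endpoint"] == rule["endpoint"]) & (out[col] > rule["max_forcing"])
        out.loc[mask, "excluded"] = True
        return out
    if not rule:
        return out
    raise ValueError(f"malformed outlier rule: {rule!r}")
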