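"""Synthetic experiment generator.

Emulates a single-shrub winter chilling-forcing trial: a 10-min outdoor
temperature log with winter daily means mostly between 0 and 10 C and a
mid-January cold spell, a near-constant indoor log around 22.5 C, a
15-cutting schedule, and per-twig BBCH trajectories driven by a
negative-exponential chilling-forcing law with level-specific noise and
chilling-dependent mortality.  Everything is deterministic given a seed, so
the module doubles as the test fixture factory for the whole pipeline.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import AccumulationSpec, accumulate
from .types import (
    BBCH_STAGES,
    LEAFOUT_STAGE,
    CuttingSchedule,
    TemperatureSeries,
    TruthModel,
    TwigRecord,
)

__all__ = [
    "ColdSpell",
    "OutdoorParams",
    "generate_outdoor_temperature",
    "generate_indoor_temperature",
    "default_schedule",
    "default_truth_model",
    "simulate_twigs",
    "inject_missingness",
    "generate_experiment",
]


@dataclass
class ColdSpell:
    """A window of depressed baseline temperature (``depression`` > 0 cools)."""

    start: dt.date
    end: dt.date  # inclusive
    depression: float


@dataclass
class OutdoorParams:
    """Shape parameters of the outdoor generator.

    The series is baseline(t) + diurnal sinusoid + AR(1) noise, minus any
    cold-spell depressions.  ``baseline`` is either a constant or anchor
    points (date, mean C) interpolated linearly — the default anchors give a
    mild central-European winter drifting into spring.
    """

    baseline: float | Sequence[tuple[dt.date, float]] = (
        (dt.date(2015, 11, 1), 6.0),
        (dt.date(2015, 12, 1), 4.0),
        (dt.date(2016, 1, 1), 3.0),
        (dt.date(2016, 2, 1), 4.0),
        (dt.date(2016, 3, 1), 6.0),
        (dt.date(2016, 4, 1), 10.0),
        (dt.date(2016, 5, 31), 16.0),
    )
    diurnal_amplitude: float = 3.0
    ar1_sd: float = 1.5
    ar1_phi: float = 0.97  # per 10-min step; ~hours-scale decorrelation
    cold_spells: Sequence[ColdSpell] = field(
        default_factory=lambda: (ColdSpell(dt.date(2016, 1, 16), dt.date(2016, 1, 24), 7.0),)
    )


def _timestamps(start: dt.date, end: dt.date, resolution_minutes: int) -> pd.DatetimeIndex:
    if end <= start:
        raise ValueError(f"non-positive span: {start} .. {end}")
    return pd.date_range(
        pd.Timestamp(start),
        pd.Timestamp(end) + pd.Timedelta(days=1),
        freq=f"{resolution_minutes}min",
        inclusive="left",
    )


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -phi], eps)


def generate_outdoor_temperature(
    start: dt.date,
    end: dt.date,
    params: Optional[OutdoorParams] = None,
    seed: int = 0,
    resolution_minutes: int = 10,
) -> TemperatureSeries:
    """Generate the outdoor 10-min temperature log over [start, end].

    Daily-mean structure comes from the baseline anchors and cold-spell
    depressions; the diurnal sinusoid (warmest mid-afternoon) and AR(1)
    noise are mean-zero at the daily scale, so generated daily means track
    the configured baseline.
    """
    params = params or OutdoorParams()
    if params.diurnal_amplitude < 0 or params.ar1_sd < 0:
        raise ValueError("amplitude and noise sd must be >= 0")
    idx = _timestamps(start, end, resolution_minutes)
    t_days = (idx - idx[0]) / pd.Timedelta(days=1)

    if np.isscalar(params.baseline):
        base = np.full(len(idx), float(params.baseline))
    else:
        anchors = sorted(params.baseline)
        xs = np.array([(d - start).days for d, _ in anchors], dtype=float)
        ys = np.array([v for _, v in anchors], dtype=float)
        base = np.interp(np.asarray(t_days), xs, ys)

    hours = idx.hour + idx.minute / 60.0
    diurnal = -params.diurnal_amplitude * np.cos(2 * np.pi * (hours - 2.0) / 24.0)
    # peak at 14:00, coldest at 02:00

    rng = np.random.default_rng(seed)
    noise = _ar1(len(idx), params.ar1_phi, params.ar1_sd, rng)

    temp = base + np.asarray(diurnal) + noise
    dates = idx.date
    for spell in params.cold_spells:
        mask = (dates >= spell.start) & (dates <= spell.end)
        temp[mask] -= spell.depression

    rh = np.clip(92.0 - 0.15 * np.asarray(t_days) + noise, 30.0, 100.0)
    data = pd.DataFrame({"temp_c": temp, "rh_pct": rh}, index=idx)
    data.index.name = "timestamp"
    return TemperatureSeries("outdoor", data, resolution_minutes)


def generate_indoor_temperature(
    start: dt.date,
    end: dt.date,
    mean: float = 22.5,
    sd: float = 0.4,
    seed: int = 0,
    resolution_minutes: int = 10,
) -> TemperatureSeries:
    """Generate a stationary indoor log fluctuating around ``mean`` C."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    idx = _timestamps(start, end, resolution_minutes)
    rng = np.random.default_rng(seed)
    temp = mean + _ar1(len(idx), 0.9, sd, rng)
    rh = np.clip(45.0 + _ar1(len(idx), 0.9, 2.0, rng), 20.0, 80.0)
    data = pd.DataFrame({"temp_c": temp, "rh_pct": rh}, index=idx)
    data.index.name = "timestamp"
    return TemperatureSeries("indoor", data, resolution_minutes)


#: The experiment's cutting calendar: 15 cuttings from 21 Nov 2015 to
#: 14 Mar 2016, with two extra observation-only visits.
_CUTTING_DATES = (
    (1, dt.date(2015, 11, 21)),
    (2, dt.date(2015, 11, 28)),
    (3, dt.date(2015, 12, 5)),
    (4, dt.date(2015, 12, 12)),
    (5, dt.date(2015, 12, 19)),
    (6, dt.date(2015, 12, 27)),
    (7, dt.date(2016, 1, 4)),
    (8, dt.date(2016, 1, 10)),
    (9, dt.date(2016, 1, 17)),
    (10, dt.date(2016, 1, 25)),
    (11, dt.date(2016, 2, 5)),
    (12, dt.date(2016, 2, 14)),
    (13, dt.date(2016, 2, 24)),
    (14, dt.date(2016, 3, 8)),
    (15, dt.date(2016, 3, 14)),
)


def default_schedule() -> CuttingSchedule:
    """The default 15-cutting winter schedule (21 Nov 2015 – 22 Mar 2016)."""
    return CuttingSchedule(
        start_date=dt.date(2015, 11, 21),
        cuttings=_CUTTING_DATES,
        end_date=dt.date(2016, 3, 22),
        extra_observation_dates=(dt.date(2016, 1, 20), dt.date(2016, 3, 22)),
    )


def default_truth_model() -> TruthModel:
    """Default generative law with heteroscedastic level noise.

    Noise standard deviations shrink with cutting index (early, low-chill
    cuttings are the most variable), in degree-days.
    """
    sds = {i: 8.0 + 37.0 * np.exp(-0.30 * (i - 1)) for i in range(1, 16)}
    return TruthModel(noise_scale_by_level=sds)


def _chilling_by_cutting(
    schedule: CuttingSchedule, outdoor: TemperatureSeries
) -> dict[int, float]:
    spec = AccumulationSpec("subdaily", 5.0, "chilling")
    start = dt.datetime.combine(schedule.start_date, dt.time())
    out = {}
    for i, d in schedule.cuttings:
        if d == schedule.start_date:
            out[i] = 0.0
        else:
            out[i] = accumulate(outdoor, (start, dt.datetime.combine(d, dt.time())), spec)
    return out


def simulate_twigs(
    schedule: CuttingSchedule,
    outdoor: TemperatureSeries,
    indoor: TemperatureSeries,
    truth: TruthModel,
    n_s: int = 10,
    n_c: int = 5,
    seed: int = 0,
) -> list[TwigRecord]:
    """Simulate per-twig BBCH trajectories for both chilling treatments.

    Shrub twigs (S) are cut at every cutting date; container twigs (C) start
    at cutting 2 (the containers were filled on day one).  Each live twig
    draws one requirement perturbation per its cutting level; its BBCH stage
    at a visit is the highest stage whose forcing requirement is met by the
    degree-days accumulated indoors since cutting.  Dying twigs stall at a
    low stage and are flagged dead at a lagged visit; twigs below leaf-out
    at the final visit are censored.
    """
    start_dt = dt.datetime.combine(schedule.start_date, dt.time())
    end_dt = dt.datetime.combine(schedule.end_date, dt.time())
    if not outdoor.covers(start_dt, end_dt):
        raise ValueError("outdoor series does not cover the schedule span")
    if not indoor.covers(start_dt, end_dt):
        raise ValueError("indoor series does not cover the schedule span")

    rng = np.random.default_rng(seed)
    chill = _chilling_by_cutting(schedule, outdoor)
    obs_dates = schedule.observation_dates()
    force_spec = AccumulationSpec("subdaily", 5.0, "forcing")

    # forcing accumulated indoors from each cutting date to each later visit
    forcing_cache: dict[tuple[int, dt.date], float] = {}
    for i, cut_date in schedule.cuttings:
        cut_dt = dt.datetime.combine(cut_date, dt.time())
        for od in obs_dates:
            if od < cut_date:
                continue
            if od == cut_date:
                forcing_cache[(i, od)] = 0.0
            else:
                forcing_cache[(i, od)] = accumulate(
                    indoor, (cut_dt, dt.datetime.combine(od, dt.time())), force_spec
                )

    live_stages = [s for s in BBCH_STAGES if s > 0]
    records: list[TwigRecord] = []
    for i, cut_date in schedule.cuttings:
        visits = [d for d in obs_dates if d >= cut_date]
        p_death = truth.death_probability(chill[i])
        sd = truth.noise_scale(i)
        for treatment, n in (("S", n_s), ("C", n_c)):
            if treatment == "C" and i == 1:
                continue  # containers are filled, not sampled, on day one
            for j in range(1, n + 1):
                twig_id = f"{treatment}{i:02d}-{j:02d}"
                eps = rng.normal(0.0, sd) if sd > 0 else 0.0
                dies = rng.random() < p_death
                death_due = cut_date + dt.timedelta(days=truth.death_lag_days)

                reqs = {
                    s: truth.requirement(chill[i], s, treatment) + eps
                    for s in live_stages
                }
                observations: list[tuple[dt.date, Optional[int]]] = []
                status, status_date = "censored", schedule.end_date
                for d in visits:
                    f = forcing_cache[(i, d)]
                    stage = 0
                    for s in live_stages:
                        if f >= max(reqs[s], 0.0):
                            stage = s
                    if dies:
                        stage = min(stage, truth.death_stage_cap)
                        if d >= death_due:
                            observations.append((d, stage))
                            status, status_date = "dead", d
                            break
                    observations.append((d, stage))
                    if stage >= LEAFOUT_STAGE:
                        status, status_date = "leafout", d
                        break  # removed from the experiment at leaf out
                if dies and status == "censored":
                    # death flagged at the last visit if the lag ran past it
                    status, status_date = "dead", visits[-1]
                records.append(
                    TwigRecord(twig_id, treatment, i, cut_date, observations, status, status_date)
                )
    return records


def inject_missingness(
    records: list[TwigRecord],
    series: TemperatureSeries,
    n_missing_days: int = 1,
    n_missing_obs: int = 0,
    seed: int = 0,
) -> tuple[list[TwigRecord], TemperatureSeries]:
    """Knock out whole logger days and interior BBCH entries, reproducibly.

    Logger days become ``NaN`` samples (interior days only, so linear
    imputation is well-posed); BBCH entries become missing markers at
    interior visits of live trajectories.  Inputs are not mutated.
    """
    rng = np.random.default_rng(seed)
    series = series.copy()
    days = sorted(set(series.data.index.date))
    interior = days[1:-1]
    if n_missing_days > len(interior):
        raise ValueError("not enough interior days to remove")
    if n_missing_days:
        drop = rng.choice(len(interior), size=n_missing_days, replace=False)
        drop_days = {interior[k] for k in drop}
        mask = np.isin(series.data.index.date, list(drop_days))
        series.data.loc[mask, "temp_c"] = np.nan

    new_records = [
        TwigRecord(r.twig_id, r.treatment, r.cutting_index, r.cutting_date,
                   list(r.observations), r.status, r.status_date)
        for r in records
    ]
    if n_missing_obs:
        candidates = [
            (ri, oi)
            for ri, r in enumerate(new_records)
            for oi in range(1, len(r.observations) - 1)
            if r.observations[oi][1] is not None
        ]
        if n_missing_obs > len(candidates):
            raise ValueError("not enough interior observations to blank")
        pick = rng.choice(len(candidates), size=n_missing_obs, replace=False)
        for k in pick:
            ri, oi = candidates[k]
            d, _ = new_records[ri].observations[oi]
            new_records[ri].observations[oi] = (d, None)
    return new_records, series


def sample_requirements(
    truth: TruthModel,
    chilling_by_level: dict[int, float],
    n_per_level: int = 10,
    stage: int = 7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (chilling, forcing) pairs straight from the truth law.

    Bypasses the visit machinery: each row is the exact stage requirement
    plus one level-noise draw, clipped at zero.  This is the generative
    model the exponential fit assumes, so it is the right input for
    parameter-recovery experiments at the experiment's scale.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for level, chill in sorted(chilling_by_level.items()):
        sd = truth.noise_scale(level)
        base = truth.requirement(chill, stage)
        eps = rng.normal(0.0, sd, size=n_per_level) if sd > 0 else np.zeros(n_per_level)
        xs.append(np.full(n_per_level, chill))
        ys.append(np.maximum(base + eps, 0.0))
    return np.concatenate(xs), np.concatenate(ys)


def generate_experiment(
    seed: int = 0,
    schedule: Optional[CuttingSchedule] = None,
    truth: Optional[TruthModel] = None,
    n_s: int = 10,
    n_c: int = 5,
):
    """Convenience: full synthetic experiment (schedule, series, records).

    Derives independent sub-seeds for the outdoor log, indoor log and twig
    simulation from ``seed``.
    """
    schedule = schedule or default_schedule()
    truth = truth or default_truth_model()
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    outdoor = generate_outdoor_temperature(
        schedule.start_date, schedule.end_date, seed=seeds[0]
    )
    indoor = generate_indoor_temperature(
        schedule.start_date, schedule.end_date, seed=seeds[1]
    )
    records = simulate_twigs(schedule, outdoor, indoor, truth, n_s, n_c, seeds[2])
    return schedule, outdoor, indoor, truth, records
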