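"""Core domain types for the cut-twig chilling-forcing analysis.

The experiment these types model: dormant twigs of a woody shrub accumulate
*chilling* outdoors (time below a temperature threshold) and, once moved
indoors on one of several staggered cutting dates, accumulate *forcing*
(degree-days above a threshold) until buds reach successive BBCH
developmental stages.  The less chilling a twig received, the more forcing
it needs — a negative-exponential relationship.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Valid BBCH codes recorded in the experiment, in developmental order:
#: 0 winter dormancy, 1 beginning of bud swelling, 3 end of bud swelling,
#: 7 beginning of bud breaking, 9 green tips, 10 mouse-ear, 11 first leaves
#: unfolded, 12 two first leaves.
BBCH_STAGES: tuple[int, ...] = (0, 1, 3, 7, 9, 10, 11, 12)

#: BBCH code at or beyond which a twig counts as having leafed out.
LEAFOUT_STAGE: int = 12

#: Developmental endpoints for which chilling/forcing rows are built.
ENDPOINT_STAGES: Mapping[str, int] = {
    "bbch7": 7,
    "bbch9": 9,
    "bbch11": 11,
    "leafout": LEAFOUT_STAGE,
}
ENDPOINTS: tuple[str, ...] = ("dead", "bbch7", "bbch9", "bbch11", "leafout")


def stage_ordinal(code: int) -> int:
    """Position of a BBCH code on the ordinal stage scale (0..7)."""
    try:
        return BBCH_STAGES.index(code)
    except ValueError:
        raise ValueError(f"invalid BBCH code {code!r}; valid codes: {BBCH_STAGES}")


@dataclass
class TemperatureSeries:
    """A regularly sampled air-temperature record for one location.

    Parameters
    ----------
    location
        ``"outdoor"`` (chilling environment) or ``"indoor"`` (forcing
        environment).
    data
        DataFrame indexed by a strictly increasing naive
        :class:`~pandas.DatetimeIndex`, with a ``temp_c`` column and an
        optional ``rh_pct`` relative-humidity column.  ``NaN`` in
        ``temp_c`` marks a missing sample (e.g. a logger outage) awaiting
        imputation.
    resolution_minutes
        Nominal sampling interval; each sample represents this much time.
    """

    location: str
    data: pd.DataFrame
    resolution_minutes: int = 10

    def __post_init__(self) -> None:
        if self.location not in ("outdoor", "indoor"):
            raise ValueError(f"unknown location {self.location!r}")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("TemperatureSeries.data must have a DatetimeIndex")
        if "temp_c" not in self.data.columns:
            raise ValueError("TemperatureSeries.data must have a 'temp_c' column")
        if len(self.data) and not self.data.index.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate timestamps in temperature series")
        if np.isinf(self.data["temp_c"].to_numpy()).any():
            raise ValueError("temperatures must be finite")

    @property
    def temps(self) -> pd.Series:
        return self.data["temp_c"]

    @property
    def start(self) -> dt.datetime:
        return self.data.index[0].to_pydatetime()

    @property
    def end(self) -> dt.datetime:
        """One nominal interval past the last sample (exclusive span end)."""
        return (self.data.index[-1] + pd.Timedelta(minutes=self.resolution_minutes)).to_pydatetime()

    def covers(self, start: dt.datetime, end: dt.datetime) -> bool:
        return self.start <= start and end <= self.end

    def copy(self) -> "TemperatureSeries":
        return TemperatureSeries(self.location, self.data.copy(), self.resolution_minutes)


@dataclass
class CuttingSchedule:
    """The experiment calendar: when chilling started, when twigs were cut.

    ``start_date`` is the chilling origin (all chilling windows open here);
    each cutting date ends outdoor chilling and starts indoor forcing for the
    twigs cut that day.  ``extra_observation_dates`` are visits on which BBCH
    was recorded but no twigs were cut.
    """

    start_date: dt.date
    cuttings: Sequence[tuple[int, dt.date]]
    end_date: dt.date
    extra_observation_dates: Sequence[dt.date] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        dates = [d for _, d in self.cuttings]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("cutting dates must be strictly increasing")
        if dates and dates[0] < self.start_date:
            raise ValueError("first cutting date must be >= start_date")
        if dates and self.end_date < dates[-1]:
            raise ValueError("end_date must be >= last cutting date")

    @property
    def n_cuttings(self) -> int:
        return len(self.cuttings)

    @property
    def cutting_dates(self) -> dict[int, dt.date]:
        return dict(self.cuttings)

    def offsets(self) -> dict[int, int]:
        """Days since experiment start for each cutting index."""
        return {i: (d - self.start_date).days for i, d in self.cuttings}

    def intervals(self) -> dict[int, int]:
        """Days between consecutive cutting dates (keyed by the later index)."""
        out: dict[int, int] = {}
        prev: Optional[dt.date] = None
        for i, d in self.cuttings:
            if prev is not None:
                out[i] = (d - prev).days
            prev = d
        return out

    def observation_dates(self) -> list[dt.date]:
        """All visit dates: cuttings, extras and the final date, sorted."""
        dates = {d for _, d in self.cuttings}
        dates.update(self.extra_observation_dates)
        dates.add(self.end_date)
        return sorted(dates)


@dataclass
class TruthModel:
    """Ground-truth generative model behind the synthetic experiment.

    A live twig cut after accumulating chilling ``x`` (subdaily chill days)
    needs ``a + b*exp(c*x) + offset(stage) + eps`` degree-days of forcing to
    reach each BBCH stage, where ``eps ~ N(0, sd(level))`` is one draw per
    twig (shared across stages, keeping trajectories monotone) with a
    chilling-level-specific standard deviation.

    Mortality: a twig dies with probability
    ``mortality_max / (1 + (x / mortality_halfscale)**2)`` — maximal with no
    chilling, halved at ``mortality_halfscale`` chill days, negligible for
    well-chilled twigs.
    """

    a: float = 80.0
    b: float = 400.0
    c: float = -0.06
    noise_scale_by_level: Mapping[int, float] = field(default_factory=dict)
    mortality_halfscale: float = 5.0
    mortality_max: float = 0.55
    stage_offsets: Mapping[int, float] = field(
        default_factory=lambda: {0: -math.inf, 1: -60.0, 3: -30.0, 7: 0.0,
                                 9: 25.0, 10: 40.0, 11: 55.0, 12: 80.0}
    )
    #: Additive forcing offset for container-stored (C) twigs; 0 means the
    #: two chilling treatments are exchangeable.
    treatment_offset_c: float = 0.0
    #: Highest BBCH stage a dying twig may show before being flagged dead.
    death_stage_cap: int = 3
    #: Days between cutting and the vitality check that flags a dead twig.
    death_lag_days: int = 14

    def __post_init__(self) -> None:
        if self.b < 0 or self.c > 0:
            raise ValueError("require b >= 0 and c <= 0 (decreasing forcing need)")
        if any(s <= 0 for s in self.noise_scale_by_level.values()):
            raise ValueError("noise scales must be positive")
        offs = [self.stage_offsets[s] for s in BBCH_STAGES if s in self.stage_offsets]
        if any(b < a for a, b in zip(offs, offs[1:])):
            raise ValueError("stage_offsets must be non-decreasing in stage order")

    def requirement(self, chilling: float, stage: int, treatment: str = "S") -> float:
        """Noise-free forcing requirement (degree-days) to reach ``stage``."""
        base = self.a + self.b * math.exp(self.c * chilling)
        off = self.stage_offsets.get(stage, 0.0)
        if treatment == "C":
            base += self.treatment_offset_c
        return max(base + off, 0.0)

    def death_probability(self, chilling: float) -> float:
        return self.mortality_max / (1.0 + (chilling / self.mortality_halfscale) ** 2)

    def noise_scale(self, cutting_index: int) -> float:
        return self.noise_scale_by_level.get(cutting_index, 0.0)


@dataclass
class TwigRecord:
    """One twig's identity, dated BBCH observations and terminal status."""

    twig_id: str
    treatment: str  # "S" fresh from shrub | "C" container-stored
    cutting_index: int
    cutting_date: dt.date
    observations: list[tuple[dt.date, Optional[int]]]
    status: str  # "dead" | "leafout" | "censored"
    status_date: dt.date

    def __post_init__(self) -> None:
        if self.treatment not in ("S", "C"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.status not in ("dead", "leafout", "censored"):
            raise ValueError(f"unknown status {self.status!r}")
        last = -1
        for d, code in self.observations:
            if code is None:
                continue
            o = stage_ordinal(code)
            if o < last:
                raise ValueError(
                    f"twig {self.twig_id}: BBCH sequence not non-decreasing at {d}"
                )
            last = o

    def observed(self) -> list[tuple[dt.date, int]]:
        """Observations with a recorded (non-missing) BBCH code."""
        return [(d, c) for d, c in self.observations if c is not None]

    def max_stage(self) -> Optional[int]:
        obs = self.observed()
        return max(c for _, c in obs) if obs else None


@dataclass
class ExpFit:
    """Fitted negative-exponential chilling-forcing law f = a + b*exp(c*x)."""

    a: float
    b: float
    c: float
    residual_sd: float
    n_rows: int
    converged: bool
    covariance: Optional[np.ndarray] = None
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


@dataclass
class LogFit:
    """Fitted logarithmic critical-forcing model GDDcrit = a + b*ln(CD)."""

    a_log: float
    b_log: float
    cd_threshold: float = 5.0
    gdd_threshold: float = 5.0
    residual_sd: float = float("nan")
    n_rows: int = 0

    def gdd_crit(self, cd) -> np.ndarray:
        cd = np.asarray(cd, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.a_log + self.b_log * np.log(cd)
        return out
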