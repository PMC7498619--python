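"""Experimental-design sensitivity analysis by subsampling.

Two reductions of the full design (15 weekly-ish cutting dates x 10 shrub
twigs) are evaluated: systematic thinning of cutting dates (every k-th week
from starting week s) and random subsampling of the twigs at each date
(without replacement, many replicates).  Each subsample is refit with the
exponential chilling-forcing law and stability is summarised as a
prediction envelope over a chilling grid — degradation concentrates at low
chilling, where the curve is steep and data are scarce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import fit_exponential, predict_forcing
from .types import ExpFit

__all__ = [
    "DateDesign",
    "StabilitySummary",
    "subsample_dates",
    "PAPER_DESIGN_GRID",
    "evaluate_date_designs",
    "subsample_twigs",
    "low_chill_width",
]

#: The (step k, start s) grid of systematic designs evaluated in the study:
#: every 2 weeks (8 or 7 dates), every 3 (5 dates), every 4 (4 dates).
PAPER_DESIGN_GRID: tuple[tuple[int, int], ...] = (
    (2, 1), (2, 2), (3, 1), (3, 2), (3, 3), (4, 1), (4, 2), (4, 3),
)


@dataclass(frozen=True)
class DateDesign:
    """A systematic cutting-date subset: every k-th index starting at s."""

    k: int
    s: int
    indices: tuple[int, ...]

    @property
    def n_dates(self) -> int:
        return len(self.indices)


def subsample_dates(K: int = 15, k: int = 1, s: int = 1) -> DateDesign:
    """Systematic design {s, s+k, s+2k, ...} within 1..K.

    The count is ceil((K - s + 1) / k); with K=15 the study grid yields
    8, 7, 5, 5, 5, 4, 4, 4 dates.
    """
    if not (1 <= s <= k <= K):
        raise ValueError(f"require 1 <= s <= k <= K, got s={s}, k={k}, K={K}")
    indices = tuple(range(s, K + 1, k))
    if not indices:
        raise ValueError("empty design")
    assert len(indices) == math.ceil((K - s + 1) / k)
    return DateDesign(k, s, indices)


def evaluate_date_designs(
    table: pd.DataFrame,
    designs: Sequence[DateDesign],
    endpoint: str = "bbch7",
    treatment: str = "S",
    definition: str = "calendar",
) -> list[tuple[Optional[DateDesign], ExpFit]]:
    """Refit the exponential law for each date design.

    The full-data fit is returned first (design ``None``) as the reference.
    A design leaving fewer than 4 distinct chilling values yields a failed
    (non-converged) fit rather than an error.
    """
    sel = (
        (table["endpoint"] == endpoint)
        & (table["treatment"] == treatment)
        & ~table["excluded"]
    )
    sub = table.loc[sel]
    have = set(sub["cutting_index"].unique())
    out: list[tuple[Optional[DateDesign], ExpFit]] = []
    x, y = sub[f"chill_{definition}"], sub[f"force_{definition}"]
    out.append((None, fit_exponential(x, y)))
    for design in designs:
        if not set(design.indices) & have:
            raise ValueError(f"table has no rows for design {design}")
        d = sub[sub["cutting_index"].isin(design.indices)]
        try:
            fit = fit_exponential(d[f"chill_{definition}"], d[f"force_{definition}"])
        except ValueError as exc:
            fit = ExpFit(np.nan, np.nan, np.nan, np.nan, len(d), False, message=str(exc))
        out.append((design, fit))
    return out


@dataclass
class StabilitySummary:
    """Replicated-fit envelope for one subsampling setting."""

    label: str
    n_keep: Optional[int]
    reps: int
    grid: np.ndarray
    env_min: np.ndarray
    env_median: np.ndarray
    env_max: np.ndarray
    params: np.ndarray  # (reps_converged, 3)
    failure_count: int
    short_dates: tuple[int, ...] = ()  # dates with fewer rows than n_keep

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chilling": self.grid, "forcing_min": self.env_min,
             "forcing_median": self.env_median, "forcing_max": self.env_max}
        )


def subsample_twigs(
    table: pd.DataFrame,
    n_keep: int,
    reps: int = 1000,
    endpoint: str = "bbch7",
    treatment: str = "S",
    definition: str = "calendar",
    seed: int = 0,
    grid: Optional[np.ndarray] = None,
    refine: bool = True,
) -> StabilitySummary:
    """Randomly keep ``n_keep`` twig rows per cutting date and refit.

    Sampling is without replacement within each cutting date; dates with
    fewer available rows than ``n_keep`` (e.g. due to mortality) contribute
    all their rows and are flagged.  Deterministic given ``seed``.
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    sel = (
        (table["endpoint"] == endpoint)
        & (table["treatment"] == treatment)
        & ~table["excluded"]
    )
    sub = table.loc[sel]
    xcol, ycol = f"chill_{definition}", f"force_{definition}"
    by_date = {
        int(i): g[[xcol, ycol]].to_numpy(dtype=float)
        for i, g in sub.groupby("cutting_index")
    }
    short = tuple(sorted(i for i, g in by_date.items() if len(g) < n_keep))
    if grid is None:
        grid = np.linspace(0.0, float(sub[xcol].max()), 101)
    rng = np.random.default_rng(seed)

    preds = np.full((reps, len(grid)), np.nan)
    params = []
    failures = 0
    for r in range(reps):
        parts = []
        for i in sorted(by_date):
            g = by_date[i]
            if len(g) <= n_keep:
                parts.append(g)
            else:
                parts.append(g[rng.choice(len(g), size=n_keep, replace=False)])
        data = np.vstack(parts)
        try:
            fit = fit_exponential(data[:, 0], data[:, 1], refine=refine)
        except ValueError:
            failures += 1
            continue
        if not fit.converged:
            failures += 1
            continue
        preds[r] = predict_forcing(fit, grid)
        params.append([fit.a, fit.b, fit.c])

    ok = ~np.isnan(preds[:, 0])
    if not ok.any():
        raise RuntimeError("no subsample fit converged")
    good = preds[ok]
    return StabilitySummary(
        label=f"n_keep={n_keep}",
        n_keep=n_keep,
        reps=reps,
        grid=np.asarray(grid),
        env_min=good.min(axis=0),
        env_median=np.median(good, axis=0),
        env_max=good.max(axis=0),
        params=np.asarray(params),
        failure_count=failures,
        short_dates=short,
    )


def low_chill_width(summary: StabilitySummary, fraction: float = 1 / 3) -> float:
    """Mean envelope width over the low-chilling part of the grid.

    The low-chilling third is where reduced designs deteriorate first, so
    its envelope width is the stability figure of merit.
    """
    n = max(int(len(summary.grid) * fraction), 1)
    return float(np.mean(summary.env_max[:n] - summary.env_min[:n]))
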