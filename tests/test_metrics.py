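"""Accumulation metrics: worked examples, brute-force oracles, invariants."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twigchill.metrics import (
    AccumulationSpec,
    accumulate,
    daily_means,
    impute_bbch,
    impute_logger_gap,
)
from twigchill.types import BBCH_STAGES, TemperatureSeries, TwigRecord

from conftest import constant_series

D0 = dt.date(2016, 1, 1)
CHILL = AccumulationSpec("subdaily", 5.0, "chilling")
FORCE = AccumulationSpec("subdaily", 5.0, "forcing")


def series_from_values(values, start=D0, resolution=10, location="outdoor"):
    idx = pd.date_range(pd.Timestamp(start), periods=len(values),
                        freq=f"{resolution}min", name="timestamp")
    return TemperatureSeries(location, pd.DataFrame({"temp_c": values}, index=idx),
                             resolution)


def brute_force_accumulate(series, window, spec):
    """Independent per-sample loop oracle for the subdaily definitions."""
    total = 0.0
    dt_days = series.resolution_minutes / 1440.0
    for ts, t in series.temps.items():
        if window[0] <= ts.to_pydatetime() < window[1]:
            if spec.role == "chilling" and t < spec.threshold:
                total += dt_days
            elif spec.role == "forcing" and t >= spec.threshold:
                total += (t - spec.threshold) * dt_days
    return total


class TestDailyMeans:
    def test_constant_day(self):
        s = constant_series(D0, D0 + dt.timedelta(days=1), 3.0)
        assert daily_means(s)["tmean"].iloc[0] == 3.0

    def test_half_cold_half_warm(self):
        vals = [0.0] * 72 + [10.0] * 72
        s = series_from_values(vals)
        assert daily_means(s)["tmean"].iloc[0] == 5.0

    def test_matches_sum_over_count_oracle(self, rng):
        vals = rng.normal(5, 4, size=288)
        s = series_from_values(vals)
        dm = daily_means(s)["tmean"]
        for k in range(2):
            day = vals[k * 144:(k + 1) * 144]
            assert dm.iloc[k] == pytest.approx(sum(day) / len(day))

    def test_empty_rejected(self):
        s = series_from_values([3.0])
        s.data = s.data.iloc[:0]
        with pytest.raises(ValueError):
            daily_means(s)


class TestLoggerImputation:
    def test_midpoint_fill(self):
        s = series_from_values([4.0, np.nan, 6.0])
        assert impute_logger_gap(s).temps.iloc[1] == 5.0

    def test_no_gap_identity(self):
        s = series_from_values([4.0, 5.0, 6.0])
        assert impute_logger_gap(s) is s

    def test_boundary_gap_rejected(self):
        s = series_from_values([np.nan, 5.0, 6.0])
        with pytest.raises(ValueError, match="boundary"):
            impute_logger_gap(s)

    def test_one_day_gap_linear_flanks(self):
        """With linear flanks, the imputed day's mean is the midpoint of
        the flanking daily means (closed form of linear interpolation)."""
        vals = np.concatenate([
            np.linspace(0, 2, 144), np.full(144, np.nan), np.linspace(4, 6, 144),
        ])
        # make the whole valid part collinear in time
        t = np.arange(3 * 144, dtype=float)
        line = t * (6.0 / (3 * 144 - 1))
        line_gapped = line.copy()
        line_gapped[144:288] = np.nan
        s = series_from_values(line_gapped)
        filled = impute_logger_gap(s)
        dm = daily_means(filled)["tmean"]
        assert dm.iloc[1] == pytest.approx((dm.iloc[0] + dm.iloc[2]) / 2)
        # original samples untouched
        assert np.array_equal(filled.temps.to_numpy()[:144], line[:144])


def _rec(codes, start=D0):
    dates = [start + dt.timedelta(days=7 * k) for k in range(len(codes))]
    return TwigRecord("t1", "S", 1, start, list(zip(dates, codes)),
                      "censored", dates[-1])


class TestBBCHImputation:
    @pytest.mark.parametrize("codes,expected", [
        ((7, None, 9), 7),     # adjacent ordinals: round-half-down tie
        ((9, None, 9), 9),     # flat flank
        ((1, None, 9), 3),     # ordinal midpoint between 3 and 7, round down
    ])
    def test_worked_examples(self, codes, expected):
        out = impute_bbch(_rec(codes))
        assert out.observations[1][1] == expected

    def test_leading_trailing_left_missing(self):
        out = impute_bbch(_rec((None, 3, 7, None)))
        assert out.observations[0][1] is None
        assert out.observations[-1][1] is None

    def test_monotonicity_preserved(self):
        out = impute_bbch(_rec((0, None, 3, None, 10, None, 12)))
        seq = [BBCH_STAGES.index(c) for _, c in out.observations if c is not None]
        assert seq == sorted(seq)

    def test_round_half_up_alternative(self):
        out = impute_bbch(_rec((7, None, 9)), round_half_up=True)
        assert out.observations[1][1] == 9


class TestAccumulate:
    def test_constant_cold_three_days(self):
        s = constant_series(D0, D0 + dt.timedelta(days=3), 2.0)
        w = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 4))
        assert accumulate(s, w, CHILL) == pytest.approx(3.0)

    def test_room_temperature_forcing(self):
        s = constant_series(D0, D0 + dt.timedelta(days=2), 22.5, "indoor")
        w = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 3))
        assert accumulate(s, w, FORCE) == pytest.approx(35.0)

    def test_calendar_ignores_temperature(self):
        w = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 11))
        assert accumulate(None, w, AccumulationSpec("calendar", 5.0, "chilling")) == 10.0

    def test_alternating_half_days(self):
        vals = ([2.0] * 72 + [8.0] * 72) * 4
        s = series_from_values(vals)
        w = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 5))
        assert accumulate(s, w, CHILL) == pytest.approx(2.0)
        assert accumulate(s, w, FORCE) == pytest.approx(6.0)

    def test_threshold_boundary_counts_to_forcing(self):
        s = series_from_values([5.0] * 144)
        w = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 2))
        assert accumulate(s, w, CHILL) == 0.0
        assert accumulate(s, w, FORCE) == 0.0  # (5 - 5) contributes nothing

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(100):
            n_days = int(rng.integers(1, 4))
            vals = rng.normal(5, 6, size=144 * n_days)
            s = series_from_values(vals)
            w = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 1 + n_days))
            for spec in (CHILL, FORCE):
                assert accumulate(s, w, spec) == pytest.approx(
                    brute_force_accumulate(s, w, spec))

    def test_dailymean_definitions(self, rng):
        vals = np.concatenate([np.full(144, 2.0), np.full(144, 8.0), np.full(144, 5.0)])
        s = series_from_values(vals)
        w = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 4))
        assert accumulate(s, w, AccumulationSpec("dailymean", 5.0, "chilling")) == 1.0
        assert accumulate(s, w, AccumulationSpec("dailymean", 5.0, "forcing")) == 3.0

    def test_subdaily_equals_dailymean_for_daywise_constant(self, rng):
        vals = np.repeat(rng.normal(5, 4, size=5), 144)
        s = series_from_values(vals)
        w = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 6))
        assert accumulate(s, w, CHILL) == pytest.approx(
            accumulate(s, w, AccumulationSpec("dailymean", 5.0, "chilling")))

    def test_window_outside_span_rejected(self):
        s = constant_series(D0, D0 + dt.timedelta(days=2), 3.0)
        with pytest.raises(ValueError, match="outside"):
            accumulate(s, (dt.datetime(2015, 12, 1), dt.datetime(2016, 1, 2)), CHILL)

    def test_reversed_window_rejected(self):
        s = constant_series(D0, D0 + dt.timedelta(days=2), 3.0)
        with pytest.raises(ValueError, match="reversed"):
            accumulate(s, (dt.datetime(2016, 1, 2), dt.datetime(2016, 1, 1)), CHILL)


@st.composite
def temp_days(draw):
    n_days = draw(st.integers(2, 4))
    vals = draw(st.lists(st.floats(-15, 30, allow_nan=False),
                         min_size=n_days * 144, max_size=n_days * 144))
    return np.asarray(vals), n_days


class TestAccumulationProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(temp_days())
    def test_additive_over_adjacent_windows(self, data):
        vals, n_days = data
        s = series_from_values(vals)
        split = dt.datetime(2016, 1, 2)
        whole = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 1 + n_days))
        for spec in (CHILL, FORCE):
            assert accumulate(s, whole, spec) == pytest.approx(
                accumulate(s, (whole[0], split), spec)
                + accumulate(s, (split, whole[1]), spec), abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(temp_days(), st.floats(0.1, 5.0))
    def test_forcing_translation_covariance(self, data, delta):
        vals, n_days = data
        vals = np.abs(vals) + 5.0  # everything already >= threshold
        s = series_from_values(vals)
        shifted = series_from_values(vals + delta)
        w = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 1 + n_days))
        assert accumulate(shifted, w, FORCE) == pytest.approx(
            accumulate(s, w, FORCE) + delta * n_days, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(temp_days())
    def test_chilling_monotone_in_threshold(self, data):
        vals, n_days = data
        s = series_from_values(vals)
        w = (dt.datetime(2016, 1, 1), dt.datetime(2016, 1, 1 + n_days))
        c0 = accumulate(s, w, AccumulationSpec("subdaily", 0.0, "chilling"))
        c5 = accumulate(s, w, AccumulationSpec("subdaily", 5.0, "chilling"))
        assert c0 <= c5
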