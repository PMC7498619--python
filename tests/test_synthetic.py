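"""Synthetic experiment generator: determinism, structure, calibration."""

import datetime as dt

import numpy as np
import pytest

from twigchill import synthetic
from twigchill.metrics import daily_means, impute_logger_gap
from twigchill.synthetic import ColdSpell, OutdoorParams
from twigchill.types import TruthModel, stage_ordinal

from conftest import constant_series

START = dt.date(2016, 1, 1)
END = dt.date(2016, 1, 20)


class TestTemperatureGenerators:
    def test_degenerate_constant_series(self):
        s = constant_series(START, END, 3.0)
        assert np.all(s.temps.to_numpy() == 3.0)
        assert len(s.data) == 20 * 144  # 10-min samples covering [start, end]

    @pytest.mark.parametrize("gen", [
        lambda seed: synthetic.generate_outdoor_temperature(START, END, seed=seed),
        lambda seed: synthetic.generate_indoor_temperature(START, END, seed=seed),
    ])
    def test_deterministic_given_seed(self, gen):
        a, b = gen(1), gen(1)
        assert a.data.equals(b.data)
        assert not gen(2).data.equals(a.data)

    def test_cold_spell_depresses_daily_means(self):
        params = OutdoorParams(
            baseline=3.0, diurnal_amplitude=2.0, ar1_sd=0.0,
            cold_spells=(ColdSpell(dt.date(2016, 1, 8), dt.date(2016, 1, 12), 8.0),),
        )
        s = synthetic.generate_outdoor_temperature(START, END, params, seed=0)
        dm = daily_means(s)["tmean"]
        inside = dm.loc[dt.date(2016, 1, 9)]
        outside = dm.loc[dt.date(2016, 1, 5)]
        assert inside == pytest.approx(outside - 8.0, abs=1e-9)

    def test_indoor_long_run_mean_near_setpoint(self):
        s = synthetic.generate_indoor_temperature(
            dt.date(2015, 11, 1), dt.date(2016, 3, 22), mean=22.5, sd=0.5, seed=3)
        vals = s.temps.to_numpy()
        # AR(1) inflates the variance of the mean; 3 marginal sd over an
        # effective sample size of n*(1-phi)/(1+phi) is a generous band
        n_eff = len(vals) * (1 - 0.9) / (1 + 0.9)
        assert abs(vals.mean() - 22.5) < 3 * 0.5 / np.sqrt(n_eff)

    def test_indoor_sd_zero_constant(self):
        s = synthetic.generate_indoor_temperature(START, END, sd=0.0, seed=1)
        assert np.all(s.temps.to_numpy() == 22.5)

    def test_rejects_non_positive_span(self):
        with pytest.raises(ValueError, match="span"):
            synthetic.generate_outdoor_temperature(END, START, seed=0)


class TestSchedule:
    def test_table_dates_and_offsets(self, schedule):
        offsets = schedule.offsets()
        assert schedule.n_cuttings == 15
        assert schedule.start_date == dt.date(2015, 11, 21)
        assert offsets[1] == 0
        assert schedule.cutting_dates[14] == dt.date(2016, 3, 8)
        assert offsets[14] == 108
        assert schedule.end_date == dt.date(2016, 3, 22)

    def test_observation_dates_include_extras_and_end(self, schedule):
        obs = schedule.observation_dates()
        assert dt.date(2016, 1, 20) in obs
        assert obs[-1] == dt.date(2016, 3, 22)
        assert obs == sorted(obs)


class TestSimulateTwigs:
    def test_record_counts(self, experiment):
        *_, records = experiment
        s = [r for r in records if r.treatment == "S"]
        c = [r for r in records if r.treatment == "C"]
        assert len(s) == 150 and len(c) == 70
        assert all(r.cutting_index >= 2 for r in c)

    def test_deterministic(self, experiment):
        schedule, outdoor, indoor, truth, records = experiment
        again = synthetic.simulate_twigs(schedule, outdoor, indoor, truth, seed=0)
        twice = synthetic.simulate_twigs(schedule, outdoor, indoor, truth, seed=0)
        assert again == twice

    def test_bbch_non_decreasing_in_every_twig(self, experiment):
        *_, records = experiment
        for r in records:
            seq = [stage_ordinal(c) for _, c in r.observed()]
            assert all(b >= a for a, b in zip(seq, seq[1:]))

    def test_noise_free_twigs_identical_within_cutting(self, schedule):
        outdoor = constant_series(schedule.start_date, schedule.end_date, 3.0)
        indoor = constant_series(schedule.start_date, schedule.end_date, 22.5, "indoor")
        truth = TruthModel(noise_scale_by_level={}, mortality_max=0.0)
        records = synthetic.simulate_twigs(schedule, outdoor, indoor, truth, seed=1)
        for i in range(1, 16):
            trajs = {tuple(r.observations) for r in records if r.cutting_index == i}
            per_treatment = {}
            for r in records:
                if r.cutting_index == i:
                    per_treatment.setdefault(r.treatment, set()).add(tuple(r.observations))
            for tr, ts in per_treatment.items():
                assert len(ts) == 1  # all twigs of a cutting x treatment agree

    def test_leafout_implies_stage_12(self, experiment):
        *_, records = experiment
        for r in records:
            if r.status == "leafout":
                assert r.max_stage() >= 12

    def test_rejects_short_series(self, schedule, truth):
        short = constant_series(schedule.start_date, dt.date(2016, 1, 1), 3.0)
        full = constant_series(schedule.start_date, schedule.end_date, 22.5, "indoor")
        with pytest.raises(ValueError, match="cover"):
            synthetic.simulate_twigs(schedule, short, full, truth, seed=0)

    def test_mortality_fractions_match_configured_curve(self, schedule):
        """Monte-Carlo over many seeds: heavy failure with near-zero
        chilling (cuttings 1-2), under 20% once chilling accrues."""
        outdoor = synthetic.generate_outdoor_temperature(
            schedule.start_date, schedule.end_date, seed=11)
        indoor = synthetic.generate_indoor_temperature(
            schedule.start_date, schedule.end_date, seed=12)
        truth = synthetic.default_truth_model()
        early, early_n, later, later_n = 0, 0, 0, 0
        for seed in range(200):
            records = synthetic.simulate_twigs(
                schedule, outdoor, indoor, truth, n_s=2, n_c=1, seed=seed)
            for r in records:
                dead = r.status == "dead"
                if r.cutting_index <= 2:
                    early += dead
                    early_n += 1
                else:
                    later += dead
                    later_n += 1
        assert 0.3 <= early / early_n <= 0.7
        assert later / later_n < 0.2
        # and the empirical curve tracks the configured probabilities
        chill = synthetic._chilling_by_cutting(schedule, outdoor)
        p1 = truth.death_probability(chill[1])
        assert p1 == pytest.approx(truth.mortality_max)


class TestMissingness:
    def test_one_missing_day(self, experiment):
        schedule, outdoor, indoor, truth, records = experiment
        recs2, series2 = synthetic.inject_missingness(records, outdoor,
                                                      n_missing_days=1, seed=5)
        nan_days = {d for d, v in zip(series2.data.index.date,
                                      series2.temps.isna()) if v}
        assert len(nan_days) == 1
        assert outdoor.temps.notna().all()  # input untouched

    def test_zero_missing_obs_identity(self, experiment):
        schedule, outdoor, *_ , records = experiment
        recs2, _ = synthetic.inject_missingness(records, outdoor,
                                                n_missing_days=0,
                                                n_missing_obs=0, seed=5)
        assert recs2 == records

    def test_missing_obs_count_and_reproducibility(self, experiment):
        schedule, outdoor, *_, records = experiment
        recs_a, _ = synthetic.inject_missingness(records, outdoor, 0, 10, seed=9)
        recs_b, _ = synthetic.inject_missingness(records, outdoor, 0, 10, seed=9)
        assert recs_a == recs_b
        n_missing = sum(
            1 for r in recs_a for _, c in r.observations if c is None
        ) - sum(1 for r in records for _, c in r.observations if c is None)
        assert n_missing == 10

    def test_roundtrip_with_logger_imputation(self, experiment):
        """A knocked-out logger day is restored near-exactly when the
        surrounding temperatures vary slowly."""
        schedule, outdoor, *_ , records = experiment
        _, series2 = synthetic.inject_missingness(records, outdoor, 1, 0, seed=3)
        restored = impute_logger_gap(series2)
        assert restored.temps.notna().all()
        gap = series2.temps.isna()
        # interpolation is exact at the (untouched) flanks and bounded inside
        flank_lo = outdoor.temps[~gap].min()
        flank_hi = outdoor.temps[~gap].max()
        assert restored.temps[gap].between(flank_lo, flank_hi).all()
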