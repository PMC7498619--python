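import datetime as dt

import numpy as np
import pytest

from twigchill import dataset, synthetic
from twigchill.metrics import daily_means


@pytest.fixture(scope="session")
def schedule():
    return synthetic.default_schedule()


@pytest.fixture(scope="session")
def experiment():
    """One full synthetic experiment at the study's scale, fixed seed."""
    return synthetic.generate_experiment(seed=42)


@pytest.fixture(scope="session")
def table(experiment):
    schedule, outdoor, indoor, truth, records = experiment
    return dataset.build_table(records, outdoor, indoor, schedule)


@pytest.fixture(scope="session")
def truth(experiment):
    return experiment[3]


@pytest.fixture(scope="session")
def base_year_daily():
    """A synthetic base-year daily mean series (Nov through May)."""
    series = synthetic.generate_outdoor_temperature(
        dt.date(2015, 11, 1), dt.date(2016, 5, 31), seed=7
    )
    return daily_means(series)


@pytest.fixture(scope="session")
def chill_by_level(experiment):
    schedule, outdoor, *_ = experiment
    return synthetic._chilling_by_cutting(schedule, outdoor)


def constant_series(start, end, value, location="outdoor", resolution=10):
    """Degenerate constant-temperature series helper."""
    params = synthetic.OutdoorParams(
        baseline=float(value), diurnal_amplitude=0.0, ar1_sd=0.0, cold_spells=()
    )
    s = synthetic.generate_outdoor_temperature(start, end, params, seed=0,
                                               resolution_minutes=resolution)
    s.location = location
    return s


def truth_rows_table(truth, chill_by_level, n_per_level=10, seed=0, endpoint="bbch7"):
    """Analysis-style table drawn straight from the truth law.

    Bypasses visit discretization so fitted curves are unbiased estimates of
    the truth curve — the right substrate for parameter-recovery and
    design-deviation checks.  All definition columns carry the same values.
    """
    import pandas as pd
    from twigchill.synthetic import sample_requirements

    x, y = sample_requirements(truth, chill_by_level, n_per_level, seed=seed)
    levels = np.repeat(sorted(chill_by_level), n_per_level)
    return pd.DataFrame({
        "twig_id": [f"S{l:02d}-{k}" for k, l in enumerate(levels)],
        "treatment": "S",
        "cutting_index": levels,
        "endpoint": endpoint,
        "chill_subdaily": x, "chill_dailymean": x, "chill_calendar": x,
        "force_subdaily": y, "force_dailymean": y, "force_calendar": y,
        "excluded": False,
    })


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
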