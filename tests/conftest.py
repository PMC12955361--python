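import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pa1c.config import SimulationConfig
from pa1c.simulate import simulate_cohort

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_subjects=10, seed=7)


@pytest.fixture(scope="session")
def cohort(small_config):
    """A small simulated cohort with default (noisy) study conditions."""
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = SimulationConfig(
        n_subjects=5, seed=3, a1c_assay_cv_lab=0.0, a1c_assay_cv_poc=0.0
    )
    return cfg, simulate_cohort(cfg)


def make_trace_frame(rows):
    """Readings table from (subject, sensor, timestamp, glucose) tuples."""
    return pd.DataFrame(
        rows, columns=["subject_id", "sensor_index", "timestamp", "glucose_mgdl"]
    )


def regular_times(start: str, n: int, minutes: int = 15) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n, freq=f"{minutes}min", tz="UTC")
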