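import numpy as np
import pandas as pd
import pytest

from anomviol import AnomalyParams, study_calendar
from anomviol.pipeline import run_fixture


def make_classified_frame(n_days: int, start: str = "2011-01-01", **columns) -> pd.DataFrame:
    """A minimal classified panel with neutral labels, overridable per column."""
    idx = study_calendar(start, pd.Timestamp(start) + pd.Timedelta(days=int(n_days * 1.01) + 10))[:n_days]
    base = {
        "apparent_temperature_mean": np.full(n_days, 15.0),
        "temperature_mean": np.full(n_days, 16.0),
        "precipitation_sum": np.zeros(n_days),
        "temp_anomaly": np.full(n_days, "none", dtype=object),
        "rain_anomaly": np.full(n_days, "none", dtype=object),
        "season": np.full(n_days, "shoulder", dtype=object),
        "weekend": np.zeros(n_days, dtype=bool),
        "baseline_complete": np.ones(n_days, dtype=bool),
        "temp_z": np.zeros(n_days),
    }
    base.update(columns)
    return pd.DataFrame(base, index=idx)


@pytest.fixture(scope="session")
def default_params() -> AnomalyParams:
    return AnomalyParams()


@pytest.fixture(scope="session")
def kha_run():
    """One full khayelitsha-like fixture analysis, shared across tests."""
    return run_fixture("khayelitsha-like", seed=3)
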