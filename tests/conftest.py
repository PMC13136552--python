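import warnings

import pandas as pd
import pytest

from branchcarbon import demo_scenario, run_pipeline
from branchcarbon.synthetic import generate_temperature_series


@pytest.fixture(scope="session")
def scenario():
    return demo_scenario(seed=7)


@pytest.fixture(scope="session")
def temperature(scenario):
    return generate_temperature_series(scenario)


@pytest.fixture(scope="session")
def pipeline_run(scenario, tmp_path_factory):
    """One full pipeline run on the demo scenario, shared across tests."""
    outdir = tmp_path_factory.mktemp("run")
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # the demo scenario must run clean
        return run_pipeline(scenario, outdir)


def constant_daily_series(year: int, value: float) -> pd.Series:
    """Daily series of one constant value over a calendar year."""
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    return pd.Series(value, index=idx, name="a_branch")
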