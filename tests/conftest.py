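import dataclasses

import pandas as pd
import pytest

from mptflux.synthetic import SyntheticConfig, generate, scenario_library


@pytest.fixture(scope="session")
def scenarios():
    return scenario_library()


@pytest.fixture(scope="session")
def threshold_series(scenarios):
    """90-day series with u*-dependent suppression (seed 1) plus truth."""
    return generate(scenarios["threshold_only"], seed=1)


@pytest.fixture(scope="session")
def clean_series(scenarios):
    """90-day series with no u* dependence (seed 1) plus truth."""
    return generate(scenarios["no_dependence"], seed=1)


@pytest.fixture(scope="session")
def drainage_series(scenarios):
    """90-day series with threshold suppression and midnight drainage."""
    return generate(scenarios["threshold_plus_drainage"], seed=1)


@pytest.fixture(scope="session")
def identity_series(scenarios):
    """Noiseless, gap-free, unsuppressed 90-day series."""
    return generate(scenarios["identity"], seed=1)


def night_records(series):
    night = series.night
    return night[night["qc"] == "observed"][["nee", "ta", "ustar"]]


@pytest.fixture()
def tmp_csv(tmp_path):
    def write(text, name="flux.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
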