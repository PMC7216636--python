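import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from dyadema import pipeline, simulate  # noqa: E402


@pytest.fixture(scope="session")
def small_config():
    """Small but structurally complete study: 25 dyads, 2 waves."""
    return dataclasses.replace(simulate.GeneratorConfig(),
                               n_dyads=25, n_waves=2, seed=11)


@pytest.fixture(scope="session")
def tiny_study():
    """Fully rendered 6-dyad, 1-wave study with epoch streams."""
    gen = dataclasses.replace(simulate.GeneratorConfig(),
                              n_dyads=6, n_waves=1, seed=9)
    return simulate.simulate_study(gen, 9)


@pytest.fixture(scope="session")
def tiny_processed(tiny_study):
    classified, valid_days = pipeline.classify_study(
        tiny_study.series, tiny_study.child_ages)
    analysis, funnel, metrics = pipeline.analysis_from_study(
        tiny_study.prompts, tiny_study.pairs, classified, valid_days,
        tiny_study.covariates)
    return {"classified": classified, "valid_days": valid_days,
            "analysis": analysis, "funnel": funnel, "metrics": metrics}


def make_epoch_index(start="2015-01-05 00:00:00", n=2880):
    return pd.date_range(start, periods=n, freq="30s")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
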