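import warnings

import numpy as np
import pytest

from covertrace import (
    CohortSimConfig,
    PhoriaTraceParams,
    compute_metrics,
    simulate_cohort,
    simulate_phoria_trace,
)


@pytest.fixture
def noise_free_params():
    return PhoriaTraceParams(
        deviation_deg=-6.0, rate_per_s=2.0, midpoint_s=1.5, noise_sd_deg=0.0, seed=0
    )


@pytest.fixture
def noise_free_trace(noise_free_params):
    return simulate_phoria_trace(noise_free_params)


@pytest.fixture(scope="session")
def fitted_cohort():
    """One 13-subject simulated cohort with metrics computed (session-cached)."""
    records = simulate_cohort(CohortSimConfig(seed=11))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rec in records:
            rec.metrics = compute_metrics(rec.trace)
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
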