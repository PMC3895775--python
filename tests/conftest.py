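"""Shared fixtures: a reference cohort, a noisy trajectory, and its fit."""

import numpy as np
import pytest

import mwfatlas as m

#: ground truth used across the suite (modified Gompertz alpha, beta, gamma, delta)
TRUTH = np.array([0.2, 1.5, 0.008, 1e-5])
NOISE_SD = 0.012


@pytest.fixture(scope="session")
def mg():
    return m.get_model("modified_gompertz")


@pytest.fixture(scope="session")
def cohort_ages():
    return m.sample_ages(m.REFERENCE_COHORT, seed=42)


@pytest.fixture(scope="session")
def noisy_trajectory(mg, cohort_ages):
    rng = np.random.default_rng(7)
    y = np.clip(
        m.evaluate(mg, TRUTH, cohort_ages) + rng.normal(0, NOISE_SD, cohort_ages.size),
        0.0,
        1.0,
    )
    return m.TrajectoryData(ages=cohort_ages, values=y, region_label="body_cc")


@pytest.fixture(scope="session")
def noisy_fit(mg, noisy_trajectory):
    return m.fit_model(mg, noisy_trajectory, options=m.FitOptions(seed=0))


@pytest.fixture(scope="session")
def noisy_draws(mg, noisy_trajectory, noisy_fit):
    return m.wild_bootstrap(mg, noisy_trajectory, noisy_fit, n_resamples=1000, seed=3)


@pytest.fixture(scope="session")
def phantom():
    return m.make_phantom((8, 8, 4), n_regions=4, seed=11, noise_sd=NOISE_SD)
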