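"""Shared fixtures: fitted synthetic landscapes reused across the suite.

The heavy objects (fits and reconstructions of the named synthetic
landscapes) are session-scoped so each is computed once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from landscaper import (EnergyLandscape, RunConfig, SamplingModel,
                        draw_samples, fixture)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: fixed sampling seed for the session-scoped study fixtures
SEED = 42
#: default study sample count (kept modest so the suite stays fast)
N_SAMPLES = 5000


def _pipeline(name, n=N_SAMPLES, seed=SEED, **sampling_kwargs):
    land = fixture(name)
    samples = draw_samples(land, SamplingModel(n=n, seed=seed, **sampling_kwargs),
                           variant_label=name)
    fit = EnergyLandscape(samples, RunConfig()).fit()
    return land, samples, fit


@pytest.fixture(scope="session")
def two_well():
    """(landscape, samples, fit) for the symmetric two-well study fixture."""
    return _pipeline("two_well_symmetric")


@pytest.fixture(scope="session")
def two_well_bdr(two_well):
    _, _, fit = two_well
    return fit.reconstruct("bdr")


@pytest.fixture(scope="session")
def two_well_sdr(two_well):
    _, _, fit = two_well
    return fit.reconstruct("sdr")


@pytest.fixture(scope="session")
def one_well():
    return _pipeline("one_well")


@pytest.fixture(scope="session")
def nested():
    return _pipeline("nested_basin")


@pytest.fixture(scope="session")
def nested_bdr(nested):
    _, _, fit = nested
    return fit.reconstruct("bdr")


@pytest.fixture(scope="session")
def small_samples():
    """A small random sample cloud for estimator unit tests."""
    from landscaper import SampleSet

    rng = np.random.default_rng(7)
    pts = rng.uniform(-3, 3, size=(200, 2))
    energies = np.sin(pts[:, 0]) + pts[:, 1] ** 2 + rng.normal(0, 0.1, 200)
    return SampleSet(pts, energies, "small")
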