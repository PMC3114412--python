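"""Shared fixtures: seeded generators and reusable simulated datasets."""

import numpy as np
import pytest

from mvarflow import EpochedTimeSeries, simulate_var


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_ts(data, srate=128.0, t0=0.0, labels=None, condition=None):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    n = data.shape[1]
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    times = t0 + np.arange(n) / srate
    return EpochedTimeSeries(data=data, srate=srate, times=times,
                             channel_labels=labels, condition=condition)


@pytest.fixture()
def noise_ts(rng):
    """3 channels x 200 samples x 5 trials of white noise."""
    return make_ts(rng.standard_normal((3, 200, 5)))


@pytest.fixture(scope="session")
def ar1_long():
    """Univariate AR(1), a=0.5, sigma^2=1, 1e5 samples (shared, read-only)."""
    rng = np.random.default_rng(777)
    x = simulate_var(np.array([[[0.5]]]), np.eye(1), 100_000, 1, rng)
    return make_ts(x, srate=128.0)


@pytest.fixture(scope="session")
def var2ch_long():
    """Bivariate VAR(1) with x0 -> x1 coupling 0.4, long single trial."""
    rng = np.random.default_rng(888)
    coeffs = np.array([[[0.5, 0.0], [0.4, 0.3]]])
    x = simulate_var(coeffs, np.eye(2), 100_000, 1, rng)
    return coeffs, make_ts(x, srate=128.0)
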