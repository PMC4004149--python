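import numpy as np
import pytest
from hypothesis import settings

import stabcox as sc
from stabcox.cohort import standardize_matrix

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def simulate_survival(
    seed, n=60, p=6, beta=None, base_keep=0.88, n_sessions=6
):
    """Small discrete-time proportional-hazards dataset for solver tests.

    Returns (Z, times, events) with Z column-standardized.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Z, _ = standardize_matrix(X, [f"x{j}" for j in range(p)])
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = (0.8, -0.5, 0.3)[: min(3, p)]
    eta = Z @ np.asarray(beta, dtype=float)
    times = np.full(n, n_sessions, dtype=np.int64)
    events = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for s in range(1, n_sessions + 1):
            if rng.random() < 1.0 - base_keep ** np.exp(eta[i]):
                times[i], events[i] = s, 1
                break
    if events.sum() == 0:  # pragma: no cover - keeps fixtures well posed
        events[0] = 1
        times[0] = 1
    return Z, times, events


@pytest.fixture(scope="session")
def signal_config():
    """Study-condition generator with the four-predictor signal."""
    return sc.default_config(effect=0.4)


@pytest.fixture(scope="session")
def null_config():
    """Study-condition generator with no covariate effects."""
    return sc.default_config(effect=0.0)


@pytest.fixture(scope="session")
def signal_cohort(signal_config):
    return sc.generate_cohort(signal_config, seed=2)


@pytest.fixture(scope="session")
def null_cohort(null_config):
    return sc.generate_cohort(null_config, seed=11)
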