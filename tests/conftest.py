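import numpy as np
import pytest

from hulakin import CompositionSeries, TransitionMatrix, propagate
from hulakin.synth import BENZENE_PHI, BENZENE_PHOTO


@pytest.fixture(scope="session")
def benzene_phi():
    return BENZENE_PHI


@pytest.fixture(scope="session")
def photo_conditions():
    return BENZENE_PHOTO


@pytest.fixture(scope="session")
def random_transition_matrix():
    """A diagonal-heavy row-stochastic matrix with all channels open."""
    rng = np.random.default_rng(42)
    m = np.eye(4)
    for i in range(4):
        off = rng.uniform(0.01, 0.05, 3)
        m[i, [j for j in range(4) if j != i]] = off
        m[i, i] = 1.0 - off.sum()
    return TransitionMatrix(m)


@pytest.fixture(scope="session")
def four_pure_start_series(random_transition_matrix):
    """Noise-free 30-step series from each pure isomer under the fixture matrix."""
    series = []
    t = np.arange(0.0, 31.0)
    for i in range(4):
        x0 = np.zeros(4)
        x0[i] = 1.0
        frac = np.vstack([propagate(random_transition_matrix, x0, int(k)) for k in t])
        series.append(CompositionSeries(t, frac))
    return series
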