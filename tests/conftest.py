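import numpy as np
import pytest

from motorexplore import default_templates, gen_angle_traces


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_trace():
    """A 30-cycle noiseless synthetic trace with known labels."""
    m = 3
    templates = default_templates(m)
    labels = np.array([1, 2, 3] * 10)
    trace, bounds = gen_angle_traces(labels, templates, cycle_period=1.2,
                                     noise_sd=0.0, seed=1)
    return trace, bounds, labels, templates


@pytest.fixture(scope="session")
def crp_two_families(rng):
    """Two well-separated CRP curve families around 0 and 120 degrees."""
    a = rng.normal(0.0, 5.0, (60, 100))
    b = rng.normal(120.0, 5.0, (60, 100))
    X = np.vstack([a, b])
    truth = np.repeat([0, 1], 60)
    return X, truth
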