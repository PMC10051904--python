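import warnings

import numpy as np
import pytest
from scipy import stats

from fsig.entropy import default_table
from fsig.ica import whiten


@pytest.fixture(scope="session")
def table():
    """Shared entropy bound table (built once, disk-cached)."""
    return default_table(512)


def make_gennorm_sources(shapes, V, rng):
    """Standardized independent generalized-Gaussian sources, one per shape."""
    S = np.vstack([stats.gennorm.rvs(b, size=V, random_state=rng)
                   for b in shapes])
    return (S - S.mean(1, keepdims=True)) / S.std(1, ddof=1, keepdims=True)


@pytest.fixture(scope="session")
def small_mixture():
    """A 4-source mixture with known ground truth (N=4, V=5000)."""
    rng = np.random.default_rng(42)
    S = make_gennorm_sources([0.6, 1.0, 3.0, 8.0], 5000, rng)
    A = rng.standard_normal((4, 4))
    data = whiten(A @ S, 4)
    return {"S": S, "A": A, "data": data, "rng_seed": 42}


@pytest.fixture(autouse=True)
def _quiet_runtime_warnings():
    """Optimizer non-convergence / clamping warnings are expected in stress
    cases and would otherwise drown the test output."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
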