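"""Shared fixtures: small deterministic synthetic systems.

Expensive artifacts (the default ground truth and its simulated cohorts)
are session-scoped so the suite pays for them once.
"""

import numpy as np
import pytest

from hopfbrain.core import StructuralConnectome
from hopfbrain.synthetic import (
    default_ground_truth,
    make_aal_style_parcellation,
    make_multistate_cohort,
)


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth(seed=1)


@pytest.fixture(scope="session")
def cohorts(ground_truth):
    return make_multistate_cohort(ground_truth)


@pytest.fixture(scope="session")
def aal90():
    """AAL-style 90-region parcellation (interleaved L/R)."""
    return make_aal_style_parcellation(90)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_connectome(rng):
    """Dense random symmetric 12-region connectome scaled to the ceiling."""
    n = 12
    w = rng.uniform(0.1, 1.0, (n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    w *= 0.2 / w.max()
    return StructuralConnectome(w, scaled=True)


def random_fc(rng, n=20):
    """A valid random Pearson-like FC matrix (correlation of random data)."""
    data = rng.standard_normal((n + 10, n))
    r = np.corrcoef(data, rowvar=False)
    return r
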