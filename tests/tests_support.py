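"""Small helpers shared across test modules."""

import numpy as np


def random_fc_matrix(rng, n=20):
    """A valid Pearson-style FC matrix (correlations of random data)."""
    data = rng.standard_normal((n + 10, n))
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def random_distance_matrix(rng, states, symmetric=True):
    """A random states-by-states distance matrix with zero diagonal."""
    n = len(states)
    v = rng.uniform(0.0, 1.0, (n, n))
    if symmetric:
        v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 0.0)
    return v
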