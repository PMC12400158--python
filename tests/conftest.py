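import numpy as np
import pytest

from herbqc import chemo, synth


@pytest.fixture(scope="session")
def default_table():
    table, truths = synth.simulate_batch_set(seed=0)
    return table, truths


@pytest.fixture(scope="session")
def fitted_model(default_table):
    table, _ = default_table
    X, _ = chemo.preprocess(table, scaling="autoscale")
    y, _ = chemo.encode_labels(table.regions)
    return chemo.oplsda(X, y, n_orthogonal=1), X, y


@pytest.fixture()
def gaussian_trace():
    """Three well-separated Gaussians with known areas on a flat baseline."""
    t = np.arange(0.0, 10.0, 0.002)
    params = [(2.0, 0.05, 100.0), (5.0, 0.05, 40.0), (8.0, 0.08, 10.0)]
    y = np.zeros_like(t)
    for mu, sigma, area in params:
        y += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return t, y, params
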