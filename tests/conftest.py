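import numpy as np
import pytest

import kpcaig as kg


@pytest.fixture(scope="session")
def small_model():
    """RBF model on small seeded random data (no scaling, simple oracle math)."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(12, 5))
    return X, kg.fit(X, kg.KernelSpec("rbf", 0.3), q=3, scale=False)


@pytest.fixture(scope="session")
def separable():
    """Three well-separated Gaussian clusters, 10 informative of 200 features."""
    return kg.make_clustered_data(
        n=60, p=200, n_informative=10, n_clusters=3,
        separation=4.0, noise_sd=1.0, seed=1,
    )


def numeric_gradient(model, X, j, eps=1e-6):
    """Central finite differences of the projection map along coordinate j.

    Independent oracle for the analytic gradient field: perturbs the raw
    input coordinate and re-runs the full out-of-sample projection.
    """
    n = X.shape[0]
    W = np.empty((n, model.q))
    for a in range(n):
        xp, xm = X[a].copy(), X[a].copy()
        xp[j] += eps
        xm[j] -= eps
        W[a] = (kg.project(model, xp[None, :]) - kg.project(model, xm[None, :])) / (2 * eps)
    return W
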