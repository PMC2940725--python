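import numpy as np
import pytest

from popfactor.sfa import SfaModel


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_model(
    rng,
    n=4,
    p=6,
    K=2,
    variance_mode="row",
    mean_term=True,
    prior_shape=1.0,
    prior_rate=1.0,
    zero_sigma=(),
):
    """A small random-but-valid model state for oracle tests."""
    F = rng.standard_normal((K, p))
    F /= F.std(axis=1, ddof=1)[:, None]
    mu = rng.standard_normal(p) if mean_term else np.zeros(p)
    psi = rng.uniform(0.5, 2.0, size=n if variance_mode == "row" else p)
    Sigma = rng.uniform(0.2, 2.0, size=(n, K))
    for i, k in zero_sigma:
        Sigma[i, k] = 0.0
    return SfaModel(
        F=F, mu=mu, psi=psi, Sigma=Sigma,
        mean_term=mean_term, variance_mode=variance_mode,
        prior_shape=prior_shape, prior_rate=prior_rate,
    )


@pytest.fixture
def small_instance(rng):
    """(X, model) pair small enough for dense joint-Gaussian oracles."""
    n, p = 4, 6
    X = rng.standard_normal((n, p)) + 1.0
    model = make_model(rng, n=n, p=p, K=2)
    return X, model
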