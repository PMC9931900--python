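import warnings

import numpy as np
import pandas as pd
import pytest

from popimpact.mcmc import ModelSpec


@pytest.fixture(autouse=True)
def _quiet():
    """Convergence/extrapolation warnings are expected at desk-scale MCMC
    settings; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def normal_mean_spec():
    """Conjugate toy: y ~ N(mu, 1), mu ~ N(0, 10^2); closed-form posterior
    mu | y ~ N(s*ybar*n/(n*s+1) ..., ) computed in the test."""
    rng = np.random.default_rng(42)
    y = rng.normal(1.5, 1.0, size=30)

    def log_post(theta):
        theta = np.atleast_2d(theta)
        mu = theta[:, 0]
        ll = -0.5 * np.sum((y[None, :] - mu[:, None]) ** 2, axis=1)
        return ll - 0.5 * mu**2 / 100.0

    def pointwise(theta):
        theta = np.atleast_2d(theta)
        mu = theta[:, 0]
        return -0.5 * ((y[None, :] - mu[:, None]) ** 2 + np.log(2 * np.pi))

    spec = ModelSpec(
        log_post=log_post, n_params=1, names={"mu": (0, 1)},
        init=lambda r: r.normal(0, 1, size=1), pointwise_loglik=pointwise,
    )
    return spec, y


def make_lek_table(counts_by_lek: dict, distances: dict, n_before: int) -> pd.DataFrame:
    """Hand-built lek table; `counts_by_lek[lek]` is the full year series."""
    rows = []
    for lek, series in counts_by_lek.items():
        for j, c in enumerate(series, start=1):
            rows.append(
                {"lek_id": lek, "year": j, "max_count": c,
                 "distance_km": distances[lek],
                 "period": "before" if j <= n_before else "after"}
            )
    return pd.DataFrame(rows)
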