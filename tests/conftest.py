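import numpy as np
import pytest

import imputedim as im


@pytest.fixture(scope="session")
def small_complete() -> im.ResponseMatrix:
    """A 400 x 10 graded-model matrix, big enough for stable moments."""
    bank = im.sample_item_bank(10, 400, seed=7)
    return im.generate_responses(bank, seed=7)


@pytest.fixture(scope="session")
def small_incomplete(small_complete) -> im.IncompleteMatrix:
    return im.apply_mcar(small_complete, 0.15, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def mvn_with_missing(
    n: int, k: int, rate: float, rng: np.random.Generator, rho: float = 0.3
) -> im.IncompleteMatrix:
    """Correlated multivariate-normal data with an MCAR mask (test helper)."""
    cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
    x = rng.multivariate_normal(np.zeros(k), cov, size=n)
    mask = rng.random((n, k)) < rate
    # keep every column observed at least twice
    for j in range(k):
        obs = np.flatnonzero(~mask[:, j])
        if obs.size < 2:
            mask[:2, j] = False
    values = np.where(mask, np.nan, x)
    return im.IncompleteMatrix(values=values, mask=mask, nominal_rate=rate)
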