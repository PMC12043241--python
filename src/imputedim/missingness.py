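"""MCAR masking, Little's MCAR test, and the rate-exclusion gate.

Missingness is imposed cell-wise: every cell of the complete matrix is
masked independently with probability equal to the nominal rate, so the
observed rate fluctuates binomially around it.

Little's test compares the pattern-wise observed means with the EM estimate
of a common multivariate normal::

    d^2 = sum_r n_r (ybar_r - mu_r)' Sigma_r^{-1} (ybar_r - mu_r)

over the observed coordinates of each distinct missingness pattern r, with
df = sum_r p_r - k (p_r = number of observed variables in pattern r). Under
MCAR, d^2 is asymptotically chi-square(df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GaussianParams, IncompleteMatrix, ResponseMatrix, logger, substream
from .imputers import RIDGE, em_fit


@dataclass
class McarTestResult:
    chi2: float
    df: int
    p_value: float
    n_patterns: int


def apply_mcar(
    matrix: ResponseMatrix, rate: float, seed: int = 0
) -> IncompleteMatrix:
    """Mask each cell independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = substream(seed, "mask")
    mask = rng.random(matrix.values.shape) < rate
    values = np.where(mask, np.nan, matrix.values.astype(float))
    return IncompleteMatrix(values=values, mask=mask, nominal_rate=rate)


def little_mcar_test(
    inc: IncompleteMatrix,
    em_tol: float = 1e-6,
    em_max_iter: int = 1000,
    params: GaussianParams | None = None,
) -> McarTestResult:
    """Little's chi-square test of the MCAR hypothesis.

    ``params`` may carry a pre-fitted EM estimate (the ML fit with divisor
    n); otherwise EM is run here. Rows with every cell missing carry no
    information and are excluded (logged).
    """
    if not inc.mask.any():
        raise ValueError("no missing data: MCAR test undefined")
    mask = inc.mask
    x = inc.values
    all_missing = mask.all(axis=1)
    if all_missing.any():
        logger.warning(
            "Little's test: dropping %d all-missing row(s)", int(all_missing.sum())
        )
        mask = mask[~all_missing]
        x = x[~all_missing]
    n, k = x.shape

    if params is None:
        params = em_fit(
            IncompleteMatrix(values=x, mask=mask, nominal_rate=inc.nominal_rate),
            max_iter=em_max_iter,
            tol=em_tol,
        )
    mu, sigma = params.mu, params.sigma

    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    chi2 = 0.0
    df = -k
    for r in range(patterns.shape[0]):
        obs = ~patterns[r]
        rows = inverse == r
        n_r = int(rows.sum())
        ybar = x[np.ix_(rows, obs)].mean(axis=0)
        d = ybar - mu[obs]
        s_oo = sigma[np.ix_(obs, obs)]
        try:
            w = np.linalg.solve(s_oo, d)
        except np.linalg.LinAlgError:
            logger.warning("singular pattern sub-matrix; adding ridge")
            w = np.linalg.solve(s_oo + RIDGE * np.eye(int(obs.sum())), d)
        chi2 += n_r * float(d @ w)
        df += int(obs.sum())
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return McarTestResult(
        chi2=float(chi2), df=int(df), p_value=p, n_patterns=patterns.shape[0]
    )


def mcar_gate(
    results: dict[float, McarTestResult], alpha_level: float = 0.05
) -> list[float]:
    """Retain the rates whose MCAR test is non-significant (p > alpha).

    Rates with p <= alpha fail the MCAR assumption and are removed from the
    study, mirroring the exclusion step applied to the 1%, 3% and 5% rates.
    """
    if not results:
        raise ValueError("no test results to gate")
    retained = [r for r, res in sorted(results.items()) if res.p_value > alpha_level]
    removed = sorted(set(results) - set(retained))
    if removed:
        logger.info(
            "MCAR gate removed rates %s at alpha=%.3f",
            ", ".join(f"{r:.0%}" for r in removed),
            alpha_level,
        )
    return retained
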