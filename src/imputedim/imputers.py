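"""The three imputation procedures: CIM, EM and MI.

* **CIM (corrected item mean)** imputes a masked cell (i, j) as the item mean
  rescaled by the respondent's person-mean ratio over their observed items::

      x_ij = (PM_i / mean of IM over obs(i)) * IM_j

* **EM** estimates (mu, Sigma) of a joint normal by maximum likelihood with
  the expectation-maximization algorithm, then fills masked cells with their
  conditional means E[x_mis | x_obs, mu, Sigma] (no residual noise).

* **MI (multiple imputation)** runs normal-model data augmentation
  (I-step: draw missing cells from their conditional normal; P-step: draw
  (mu, Sigma) from the Jeffreys-prior posterior given the completed data),
  retains m completed datasets after burn-in, and forms a consensus dataset
  as the per-cell mean of the m raw draws.

All three round imputed values half-away-from-zero and clip to the 1..5
category range, and leave observed cells untouched. The 1-5 ordinal codes
are treated as continuous for EM/MI, mirroring standard practice for
Likert-type data, and rounded afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    GaussianParams,
    IncompleteMatrix,
    ResponseMatrix,
    logger,
    round_and_clip,
    substream,
)

EM_TOL = 1e-6
EM_MAX_ITER = 1000
RIDGE = 1e-8


@dataclass
class ImputationResult:
    """A completed matrix plus the raw (unrounded) imputations."""

    completed: ResponseMatrix
    method: str
    raw: np.ndarray  # full n x k float matrix before rounding
    mask: np.ndarray
    m_datasets: list[ResponseMatrix] | None = None
    params: GaussianParams | None = None
    raw_datasets: list[np.ndarray] | None = None

    @property
    def raw_imputes(self) -> np.ndarray:
        """Unrounded imputed values at the masked cells only."""
        return self.raw[self.mask]


def _complete(inc: IncompleteMatrix, raw: np.ndarray, method: str, **kw) -> ImputationResult:
    values = np.where(inc.mask, round_and_clip(raw), np.nan_to_num(inc.values))
    return ImputationResult(
        completed=ResponseMatrix(values.astype(np.int64)),
        method=method,
        raw=raw,
        mask=inc.mask.copy(),
        **kw,
    )


# ---------------------------------------------------------------------------
# Corrected item mean
# ---------------------------------------------------------------------------

def cim_impute(inc: IncompleteMatrix) -> ImputationResult:
    """Corrected-item-mean imputation.

    Raises if any item has no observed value. A respondent with no observed
    item has an undefined person ratio and falls back to the plain item mean
    (ratio 1); this is logged.
    """
    obs = ~inc.mask
    n_obs_item = obs.sum(axis=0)
    if np.any(n_obs_item == 0):
        j = int(np.argmax(n_obs_item == 0))
        raise ValueError(f"item {j + 1} has no observed values; CIM undefined")

    x = np.nan_to_num(inc.values)
    im = x.sum(axis=0) / n_obs_item  # item means over observed
    n_obs_person = obs.sum(axis=1)
    empty = n_obs_person == 0
    if np.any(empty):
        logger.warning(
            "CIM: %d respondent(s) with no observed items; using item means",
            int(empty.sum()),
        )
    safe = np.where(empty, 1, n_obs_person)
    pm = x.sum(axis=1) / safe  # person means over observed
    im_obs_mean = (obs * im[None, :]).sum(axis=1) / safe
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(empty, 1.0, pm / im_obs_mean)
    raw = np.where(inc.mask, ratio[:, None] * im[None, :], inc.values)
    return _complete(inc, raw, "CIM")


# ---------------------------------------------------------------------------
# Conditional-Gaussian machinery shared by EM and MI
# ---------------------------------------------------------------------------

class _PatternGroups:
    """Rows grouped by their count of missing cells, for batched solves.

    Rows in a group share the number of observed items o, so their o x o
    covariance sub-matrices stack into one (m, o, o) array and a single
    batched ``np.linalg.solve`` handles the whole group.
    """

    def __init__(self, mask: np.ndarray):
        self.n, self.k = mask.shape
        self.complete_rows = np.flatnonzero(~mask.any(axis=1))
        self.groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        counts = mask.sum(axis=1)
        for c in np.unique(counts):
            if c == 0 or c == self.k:
                continue
            rows = np.flatnonzero(counts == c)
            order = np.argsort(mask[rows], axis=1, kind="stable")
            obs_idx = np.sort(order[:, : self.k - c], axis=1)
            mis_idx = np.sort(order[:, self.k - c :], axis=1)
            self.groups.append((rows, obs_idx, mis_idx))
        self.all_missing_rows = np.flatnonzero(counts == self.k)


def _estep(
    x: np.ndarray,
    groups: _PatternGroups,
    mu: np.ndarray,
    sigma: np.ndarray,
    want_cov: bool = True,
    want_loglik: bool = True,
    draw_rng: np.random.Generator | None = None,
):
    """Conditional means (or draws) of missing cells given (mu, Sigma).

    Returns ``(xhat, cov_correction, loglik)`` where ``xhat`` is x with
    missing cells replaced by conditional means (or posterior-predictive
    draws when ``draw_rng`` is given), ``cov_correction`` is the k x k
    scatter of conditional covariances to add to ``xhat' xhat`` in the EM
    M-step, and ``loglik`` is the observed-data log-likelihood.
    """
    n, k = x.shape
    xhat = np.array(x, dtype=float)
    xhat[np.isnan(xhat)] = 0.0
    corr_flat = np.zeros(k * k)
    loglik = 0.0

    if want_loglik and groups.complete_rows.size:
        d = x[groups.complete_rows] - mu
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            chol = np.linalg.cholesky(sigma + RIDGE * np.eye(k))
        w = np.linalg.solve(chol, d.T)
        loglik += -0.5 * (
            groups.complete_rows.size * (k * np.log(2 * np.pi))
            + 2 * groups.complete_rows.size * np.log(np.diag(chol)).sum()
            + (w**2).sum()
        )

    for rows, obs_idx, mis_idx in groups.groups:
        m, o = obs_idx.shape
        c = mis_idx.shape[1]
        s_oo = sigma[obs_idx[:, :, None], obs_idx[:, None, :]]
        s_mo = sigma[mis_idx[:, :, None], obs_idx[:, None, :]]
        d = x[rows[:, None], obs_idx] - mu[obs_idx]  # (m, o)
        rhs = np.concatenate([d[:, :, None], np.swapaxes(s_mo, 1, 2)], axis=2)
        try:
            w = np.linalg.solve(s_oo, rhs)  # (m, o, 1 + c)
        except np.linalg.LinAlgError:
            logger.warning("ill-conditioned observed block; adding ridge")
            s_oo = s_oo + RIDGE * np.eye(o)[None]
            w = np.linalg.solve(s_oo, rhs)
        cond_mean = mu[mis_idx] + (s_mo @ w[:, :, :1])[:, :, 0]
        cond_cov = sigma[mis_idx[:, :, None], mis_idx[:, None, :]] - s_mo @ w[:, :, 1:]

        if draw_rng is not None:
            cond_cov_j = cond_cov + 1e-10 * np.eye(c)[None]
            try:
                chol_c = np.linalg.cholesky(cond_cov_j)
            except np.linalg.LinAlgError:
                logger.warning("conditional covariance not PSD; adding ridge")
                chol_c = np.linalg.cholesky(cond_cov_j + 1e-6 * np.eye(c)[None])
            z = draw_rng.standard_normal((m, c))
            fill = cond_mean + (chol_c @ z[:, :, None])[:, :, 0]
        else:
            fill = cond_mean
        xhat[rows[:, None], mis_idx] = fill

        if want_cov:
            lin = (mis_idx[:, :, None] * k + mis_idx[:, None, :]).ravel()
            corr_flat += np.bincount(lin, weights=cond_cov.ravel(), minlength=k * k)

        if want_loglik:
            sign, logdet = np.linalg.slogdet(s_oo)
            quad = (d[:, :, None] * w[:, :, :1]).sum(axis=(1, 2))
            loglik += -0.5 * (
                m * o * np.log(2 * np.pi) + logdet.sum() + quad.sum()
            )

    return xhat, corr_flat.reshape(k, k), loglik


def em_fit(
    inc: IncompleteMatrix,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> GaussianParams:
    """ML (mu, Sigma) of a joint normal fitted to incomplete data by EM.

    The covariance uses the ML divisor n. Iteration stops when the largest
    absolute change of any parameter drops below ``tol`` or at ``max_iter``;
    non-convergence is flagged, not raised. The observed-data log-likelihood
    trace is recorded and is non-decreasing.
    """
    obs_per_item = (~inc.mask).sum(axis=0)
    if np.any(obs_per_item < 2):
        raise ValueError("every variable must be observed at least twice")
    mask = inc.mask
    x = inc.values
    all_missing = mask.all(axis=1)
    if all_missing.any():  # such rows carry no likelihood information
        logger.warning(
            "EM: excluding %d all-missing row(s)", int(all_missing.sum())
        )
        mask = mask[~all_missing]
        x = x[~all_missing]
    groups = _PatternGroups(mask)
    n, k = x.shape

    # start from mean-imputed moments
    mu = np.nanmean(x, axis=0)
    x0 = np.where(mask, mu[None, :], x)
    sigma = np.cov(x0, rowvar=False, ddof=0) + RIDGE * np.eye(k)

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        xhat, corr, ll = _estep(x, groups, mu, sigma)
        trace.append(ll)
        mu_new = xhat.mean(axis=0)
        sigma_new = (xhat.T @ xhat + corr) / n - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        delta = max(
            np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()
        )
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    return GaussianParams(
        mu=mu,
        sigma=sigma,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
    )


def em_impute(
    inc: IncompleteMatrix, params: GaussianParams | None = None, **fit_kw
) -> ImputationResult:
    """Conditional-mean imputation under the EM-fitted normal model."""
    if params is None:
        params = em_fit(inc, **fit_kw)
    groups = _PatternGroups(inc.mask)
    xhat, _, _ = _estep(
        inc.values, groups, params.mu, params.sigma, want_cov=False, want_loglik=False
    )
    if groups.all_missing_rows.size:
        xhat[groups.all_missing_rows] = params.mu[None, :]
    raw = np.where(inc.mask, xhat, inc.values)
    return _complete(inc, raw, "EM", params=params)


# ---------------------------------------------------------------------------
# Multiple imputation by data augmentation
# ---------------------------------------------------------------------------

def mi_impute(
    inc: IncompleteMatrix,
    m: int = 100,
    iterations: int = 1000,
    burn_in: int = 200,
    seed: int = 0,
    start: GaussianParams | None = None,
) -> ImputationResult:
    """Normal-model multiple imputation with a Jeffreys prior.

    Alternates the I-step (draw missing cells from their conditional normal
    given the current (mu, Sigma)) with the P-step (draw Sigma from
    InvWishart(n-1, S) and mu from N(xbar, Sigma/n) given the completed
    data). After ``burn_in`` iterations, every ``iterations // m``-th
    completed dataset is retained until m are collected.

    ``completed`` is the consensus dataset: the per-cell mean of the m raw
    draws, rounded and clipped. ``m_datasets`` holds the m rounded datasets
    for Rubin-style per-dataset analysis.
    """
    if m < 2:
        raise ValueError("multiple imputation needs m >= 2")
    thin = max(1, iterations // m)
    rng = substream(seed, "mi")
    groups = _PatternGroups(inc.mask)
    x = inc.values
    n, k = x.shape

    if start is None:
        start = em_fit(inc, max_iter=200, tol=1e-5)
    mu, sigma = start.mu.copy(), start.sigma.copy()

    kept_raw: list[np.ndarray] = []
    total = burn_in + thin * m
    for t in range(1, total + 1):
        # I-step
        xhat, _, _ = _estep(
            x, groups, mu, sigma, want_cov=False, want_loglik=False, draw_rng=rng
        )
        if groups.all_missing_rows.size:
            z = rng.standard_normal((groups.all_missing_rows.size, k))
            chol_full = np.linalg.cholesky(sigma + RIDGE * np.eye(k))
            xhat[groups.all_missing_rows] = mu[None, :] + z @ chol_full.T
        # P-step
        xbar = xhat.mean(axis=0)
        dx = xhat - xbar
        s = dx.T @ dx
        chol_s = None
        for attempt in range(3):
            try:
                sigma = stats.invwishart.rvs(df=n - 1, scale=s, random_state=rng)
                chol_s = np.linalg.cholesky(sigma)
                break
            except np.linalg.LinAlgError:
                logger.warning("posterior covariance draw not PSD; ridging scale")
                s = s + 1e-6 * np.trace(s) / k * np.eye(k)
        if chol_s is None:  # last resort: posterior mode of Sigma
            sigma = s / (n + k + 1) + RIDGE * np.eye(k)
            chol_s = np.linalg.cholesky(sigma)
        mu = xbar + (chol_s @ rng.standard_normal(k)) / np.sqrt(n)

        if t > burn_in and (t - burn_in) % thin == 0:
            kept_raw.append(np.where(inc.mask, xhat, x))
            if len(kept_raw) == m:
                break

    raw_consensus = np.mean(kept_raw, axis=0)
    result = _complete(inc, raw_consensus, "MI")
    result.raw_datasets = kept_raw
    result.m_datasets = [
        ResponseMatrix(
            np.where(inc.mask, round_and_clip(r), np.nan_to_num(x)).astype(np.int64)
        )
        for r in kept_raw
    ]
    return result


IMPUTERS = {"CIM": cim_impute, "EM": em_impute, "MI": mi_impute}
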