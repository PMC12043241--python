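"""Unidimensionality battery: alpha, CITC, eigenvalue indices, communalities.

All principal-component quantities come from the eigen-decomposition of the
k x k Pearson correlation matrix, whose eigenvalues sum to k; the explained
variance of component c is therefore 100 * lambda_c / k. Components are
retained by the Kaiser rule (lambda > 1). Communalities are sums of squared
loadings (loading = eigenvector entry * sqrt(lambda)) over the retained
components. Factor rotation is not applied: eigenvalues, explained variance
and communalities are rotation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ResponseMatrix, logger


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, ResponseMatrix):
        return matrix.values.astype(float)
    return np.asarray(matrix, dtype=float)


@dataclass
class IndexBattery:
    """All unidimensionality indicators for one (method, rate) cell."""

    alpha: float
    citc: np.ndarray
    eigenvalues: np.ndarray  # first three, descending
    ratio_12: float
    gap_ratio: float  # (l1 - l2) / (l2 - l3), NaN when l2 == l3
    cum_variance: np.ndarray  # cumulative % for the Kaiser-retained components
    communalities: np.ndarray
    n_retained: int
    all_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def citc_mean(self) -> float:
        return float(np.nanmean(self.citc))


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum item variances / total variance).

    Sample variances use divisor n-1.
    """
    x = _as_array(matrix)
    n, k = x.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - x.var(axis=0, ddof=1).sum() / total_var))


def corrected_item_total(matrix) -> np.ndarray:
    """Pearson correlation of each item with the sum of the other items.

    Zero-variance items yield NaN (flagged) and are excluded from summary
    means by ``IndexBattery.citc_mean``.
    """
    x = _as_array(matrix)
    n, k = x.shape
    if k < 3:
        raise ValueError("corrected item-total needs at least 3 items")
    total = x.sum(axis=1)
    out = np.empty(k)
    for j in range(k):
        rest = total - x[:, j]
        sx = x[:, j].std(ddof=1)
        sr = rest.std(ddof=1)
        if sx == 0 or sr == 0:
            logger.warning("item %d has zero variance; CITC undefined", j + 1)
            out[j] = np.nan
            continue
        out[j] = np.cov(x[:, j], rest, ddof=1)[0, 1] / (sx * sr)
    return out


def pca_battery(matrix, force_one_component: bool = False) -> IndexBattery:
    """Eigenvalue indices of the inter-item Pearson correlation matrix.

    ``force_one_component`` restricts communalities and cumulative variance
    to the first component regardless of the Kaiser rule.
    """
    x = _as_array(matrix)
    n, k = x.shape
    if np.any(x.std(axis=0) == 0):
        raise ValueError("zero-variance item: correlation matrix undefined")
    corr = np.corrcoef(x, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    l1, l2, l3 = evals[:3]
    if np.isclose(l2, l3):
        logger.warning("lambda2 == lambda3: gap ratio undefined")
        gap = float("nan")
    else:
        gap = float((l1 - l2) / (l2 - l3))

    n_retained = 1 if force_one_component else max(1, int((evals > 1.0).sum()))
    loadings = evecs[:, :n_retained] * np.sqrt(np.clip(evals[:n_retained], 0, None))
    communalities = (loadings**2).sum(axis=1)
    cum_variance = 100.0 * np.cumsum(evals[:n_retained]) / k

    return IndexBattery(
        alpha=float("nan"),
        citc=np.full(k, np.nan),
        eigenvalues=evals[:3].copy(),
        ratio_12=float(l1 / l2),
        gap_ratio=gap,
        cum_variance=cum_variance,
        communalities=communalities,
        n_retained=n_retained,
        all_eigenvalues=evals.copy(),
    )


def battery_for(matrix, force_one_component: bool = False) -> IndexBattery:
    """Bundle alpha, CITC and the PCA indices for one matrix."""
    battery = pca_battery(matrix, force_one_component=force_one_component)
    battery.alpha = cronbach_alpha(matrix)
    battery.citc = corrected_item_total(matrix)
    return battery
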