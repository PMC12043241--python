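"""Shared containers and low-level helpers.

The pipeline passes three matrix containers between stages:

* :class:`ResponseMatrix` -- a complete integer response matrix (codes 1-5),
* :class:`IncompleteMatrix` -- the same matrix with MCAR holes plus its mask,
* :class:`GaussianParams` -- a multivariate-normal (mu, Sigma) estimate shared
  by EM imputation, multiple imputation and Little's MCAR test.

All containers are thin dataclasses over numpy arrays; CSV round-tripping is
done with pandas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("imputedim")

CATEGORY_MIN = 1
CATEGORY_MAX = 5

#: substream tags so each stage draws from its own independently replayable RNG
_STREAM_TAGS = {"params": 11, "responses": 23, "mask": 37, "mi": 53, "noise": 71}


def substream(seed: int, name: str) -> np.random.Generator:
    """A named child RNG of the study seed.

    Every stage (parameter draw, response draw, masking, MI sampler) gets its
    own stream so that re-running one stage with the same seed reproduces it
    regardless of what ran before.
    """
    return np.random.default_rng([int(seed), _STREAM_TAGS[name]])


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer with ties going away from zero.

    numpy's ``round`` uses banker's rounding; the SPSS-style convention used
    here rounds 2.5 -> 3.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def round_and_clip(
    raw: np.ndarray, lo: int = CATEGORY_MIN, hi: int = CATEGORY_MAX
) -> np.ndarray:
    """Half-away-from-zero rounding followed by clamping to the category range."""
    return np.clip(round_half_away(raw), lo, hi).astype(np.int64)


@dataclass
class ItemBank:
    """Graded-response-model item parameters plus the generating abilities.

    Attributes
    ----------
    a : (k,) discriminations on the latent-trait (logit) scale, all > 0.
    b : (k, 4) strictly ordered category thresholds per item.
    theta : (n,) abilities used for generation, or None before generation.
    """

    a: np.ndarray
    b: np.ndarray
    theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.b.ndim != 2 or self.b.shape != (self.a.size, 4):
            raise ValueError("b must be a (k, 4) threshold matrix")
        if np.any(self.a <= 0):
            raise ValueError("discriminations must be positive")
        if np.any(np.diff(self.b, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)

    @property
    def k(self) -> int:
        return self.a.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"item": np.arange(1, self.k + 1), "a": self.a})
        for c in range(4):
            df[f"b{c + 1}"] = self.b[:, c]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ItemBank":
        df = pd.read_csv(path)
        b = df[["b1", "b2", "b3", "b4"]].to_numpy(float)
        return cls(a=df["a"].to_numpy(float), b=b)


@dataclass
class ResponseMatrix:
    """Complete n x k integer response matrix with codes 1..5."""

    values: np.ndarray
    category_min: int = CATEGORY_MIN
    category_max: int = CATEGORY_MAX

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be 2-D")
        if np.any(np.isnan(v.astype(float))):
            raise ValueError("a ResponseMatrix has no missing cells")
        vi = v.astype(np.int64)
        if np.any(vi != v):
            raise ValueError("values must be integers")
        if vi.min() < self.category_min or vi.max() > self.category_max:
            raise ValueError(
                f"values must lie in [{self.category_min}, {self.category_max}]"
            )
        self.values = vi

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        cols = [f"item{j + 1}" for j in range(self.k)]
        pd.DataFrame(self.values, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        return cls(pd.read_csv(path).to_numpy())


@dataclass
class IncompleteMatrix:
    """A response matrix with MCAR holes: NaN at masked cells, plus the mask."""

    values: np.ndarray  # float matrix, NaN where missing
    mask: np.ndarray  # True = missing
    nominal_rate: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.array_equal(np.isnan(self.values), self.mask):
            raise ValueError("NaN cells and mask must coincide exactly")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def observed_rate(self) -> float:
        return float(self.mask.mean())

    def to_csv(self, path, mask_path=None) -> None:
        cols = [f"item{j + 1}" for j in range(self.k)]
        df = pd.DataFrame(self.values, columns=cols)
        # pandas writes NaN as an empty cell, which is the on-disk convention
        df.astype("Int64").to_csv(path, index=False)
        if mask_path is not None:
            pd.DataFrame(self.mask.astype(int), columns=cols).to_csv(
                mask_path, index=False
            )

    @classmethod
    def from_csv(cls, path, nominal_rate: float = 0.0) -> "IncompleteMatrix":
        v = pd.read_csv(path).to_numpy(dtype=float)
        return cls(values=v, mask=np.isnan(v), nominal_rate=nominal_rate)


@dataclass
class GaussianParams:
    """Multivariate-normal parameter estimate (mu, Sigma) with an EM trace."""

    mu: np.ndarray
    sigma: np.ndarray
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma must be k x k")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")
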