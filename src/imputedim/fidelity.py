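"""Distortion of imputed values relative to the original complete data.

For each (method, rate) cell the absolute difference |original - imputed|
over the masked cells is tabulated into the classes 0..4 (as percentages of
the masked-cell count). "Distortion" is the percentage of imputed cells
that differ from the original by at least one category, i.e. 100 minus the
exact-match percentage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ResponseMatrix
from .imputers import ImputationResult

DIFF_COLS = ["d0", "d1", "d2", "d3", "d4"]


def distortion_profile(
    original: ResponseMatrix,
    result: ImputationResult,
    mask: np.ndarray | None = None,
) -> pd.Series:
    """One fidelity row: difference-class percentages over the masked cells."""
    mask = result.mask if mask is None else np.asarray(mask, dtype=bool)
    if mask.shape != original.values.shape:
        raise ValueError("mask and matrix shapes differ")
    if not mask.any():
        raise ValueError("no imputed cells")
    diff = np.abs(original.values[mask] - result.completed.values[mask])
    counts = np.bincount(diff, minlength=5)[:5]
    pct = 100.0 * counts / mask.sum()
    row = pd.Series(pct, index=DIFF_COLS)
    row["distortion"] = 100.0 - row["d0"]
    row["method"] = result.method
    return row


def fidelity_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-method means over rates (the table's MEAN row)."""
    if rows.empty:
        raise ValueError("no fidelity rows")
    cols = DIFF_COLS + ["distortion"]
    return rows.groupby("method")[cols].mean()
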