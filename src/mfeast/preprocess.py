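"""Expression filtering and transformation.

The filtering rule removes features that sit below the dataset-wide median
expression ("minimum expression threshold") in more than a given fraction of
samples (default 90%). Comparisons are strict: a value counts as low only if
it is strictly below the threshold, and a feature is removed only if its
low-count strictly exceeds ``fraction * n_samples``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_io import ExpressionMatrix

__all__ = [
    "FilterReport",
    "low_expression_filter",
    "log2_transform",
    "zscore_scale",
    "median_center",
]


@dataclass
class FilterReport:
    threshold: float
    removed_ids: list[str]
    kept_ids: list[str]
    fraction_rule: float


def low_expression_filter(
    m: ExpressionMatrix, fraction: float = 0.90
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove features below the pooled-median threshold in > fraction of samples.

    The threshold is the median over *every cell* of the matrix, not a
    per-feature median.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if m.n_features == 0 or m.n_samples == 0:
        raise ValueError("cannot filter an empty matrix")
    threshold = float(np.median(m.values))
    low_counts = np.sum(m.values < threshold, axis=1)
    removed_mask = low_counts > fraction * m.n_samples
    kept_ids = [f for f, r in zip(m.feature_ids, removed_mask) if not r]
    removed_ids = [f for f, r in zip(m.feature_ids, removed_mask) if r]
    kept = ExpressionMatrix(
        kept_ids, list(m.sample_ids), m.values[~removed_mask, :],
        require_non_negative=m.require_non_negative,
    )
    return kept, FilterReport(threshold, removed_ids, kept_ids, fraction)


def log2_transform(m: ExpressionMatrix, zero_replacement: float | None = None) -> ExpressionMatrix:
    """log2-transform after replacing zeros with the smallest non-zero value.

    ``zero_replacement`` overrides the inferred epsilon (by default the
    smallest non-zero value in the whole matrix, used as-is).
    """
    if np.any(m.values < 0):
        raise ValueError("log2_transform requires non-negative values")
    nonzero = m.values[m.values > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero matrix: cannot log2-transform")
    eps = float(nonzero.min()) if zero_replacement is None else float(zero_replacement)
    vals = np.where(m.values == 0, eps, m.values)
    return ExpressionMatrix(
        list(m.feature_ids), list(m.sample_ids), np.log2(vals),
        require_non_negative=False,
    )


def zscore_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature standardization to zero mean, unit (n-1) variance.

    Constant features map to all-zeros rather than dividing by zero.
    """
    mean = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True) if m.n_samples > 1 else np.zeros_like(mean)
    sd = np.where(sd == 0, 1.0, sd)
    return ExpressionMatrix(
        list(m.feature_ids), list(m.sample_ids), (m.values - mean) / sd,
        require_non_negative=False,
    )


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's median across samples (heatmap visualization)."""
    med = np.median(m.values, axis=1, keepdims=True)
    return ExpressionMatrix(
        list(m.feature_ids), list(m.sample_ids), m.values - med,
        require_non_negative=False,
    )
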