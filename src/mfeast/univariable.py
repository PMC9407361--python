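"""Univariable filter-type feature scorers.

Four per-feature discrimination criteria for a binary comparison:

* ``roc_criterion`` — 2*|AUC - 0.5|, where AUC is the probability that a
  class-b value exceeds a class-a value (ties count 1/2). Spans [0, 1].
* ``wilcoxon_criterion`` — the absolute rank-sum z statistic (no tie
  correction in the variance). Raw scale; min-max normalized downstream.
* ``mutual_information`` — plug-in mutual information (bits) between the
  feature discretized into equal-width bins and the class label.
* ``relieff_weights`` — binary ReliefF: weights accumulate range-scaled
  feature differences to the k nearest same-class (hit) and other-class
  (miss) neighbors of every sample, under Manhattan distance over all
  features. Weights lie in [-1, 1].

Scalar functions take one feature's values ``x`` and a 0/1 label vector
``y``; ``*_scores`` variants score every row of a matrix at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .matrix_io import ComparisonDesign, ExpressionMatrix

__all__ = [
    "FeatureScoreVector",
    "roc_criterion",
    "wilcoxon_criterion",
    "mutual_information",
    "relieff_weights",
    "roc_scores",
    "wilcoxon_scores",
    "mutual_information_scores",
    "relieff_scores",
]


@dataclass
class FeatureScoreVector:
    method: str
    scores: dict[str, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.normalized:
            vals = np.array(list(self.scores.values()))
            if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
                raise ValueError(f"{self.method}: normalized scores outside [0, 1]")


def _check_binary(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    mask_a, mask_b = y == 0, y == 1
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both classes must be present")
    return mask_a, mask_b


def _auc_from_ranks(ranks: np.ndarray, mask_b: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """AUC = P(x_b > x_a) with half-credit ties, from average-tie ranks.

    ``ranks`` is (..., n); the trailing axis is samples.
    """
    u_b = ranks[..., mask_b].sum(axis=-1) - n_b * (n_b + 1) / 2
    return u_b / (n_a * n_b)


def roc_criterion(x, y) -> float:
    """Score in [0, 1]: 0 for no separation, 1 for disjoint class supports."""
    x = np.asarray(x, dtype=float)
    mask_a, mask_b = _check_binary(y)
    ranks = rankdata(x)
    auc = _auc_from_ranks(ranks, mask_b, int(mask_a.sum()), int(mask_b.sum()))
    return float(2 * abs(auc - 0.5))


def wilcoxon_criterion(x, y) -> float:
    """|z| of the Mann-Whitney U count (plain variance, no tie correction)."""
    x = np.asarray(x, dtype=float)
    mask_a, mask_b = _check_binary(y)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    ranks = rankdata(x)
    u = ranks[mask_b].sum() - n_b * (n_b + 1) / 2
    var = n_a * n_b * (n_a + n_b + 1) / 12.0
    return float(abs(u - n_a * n_b / 2) / np.sqrt(var))


def _bin_indices(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin index per cell, per row; constant rows get bin 0."""
    lo = values.min(axis=-1, keepdims=True)
    hi = values.max(axis=-1, keepdims=True)
    width = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.floor((values - lo) / width * bins).astype(int)
    idx = np.clip(idx, 0, bins - 1)
    idx[np.broadcast_to(width == 0, idx.shape)] = 0
    return idx


def _mi_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def mutual_information(x, y, bins: int = 10) -> float:
    """Plug-in MI (bits) between equal-width-binned x and the class label."""
    x = np.asarray(x, dtype=float)
    _check_binary(y)
    y = np.asarray(y)
    idx = _bin_indices(x[None, :], bins)[0]
    joint = np.zeros((bins, 2))
    np.add.at(joint, (idx, y), 1.0)
    return _mi_from_joint(joint)


def roc_scores(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise ``roc_criterion`` over a (p, n) matrix."""
    mask_a, mask_b = _check_binary(y)
    ranks = rankdata(values, axis=1)
    auc = _auc_from_ranks(ranks, mask_b, int(mask_a.sum()), int(mask_b.sum()))
    return 2 * np.abs(auc - 0.5)


def wilcoxon_scores(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    mask_a, mask_b = _check_binary(y)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    ranks = rankdata(values, axis=1)
    u = ranks[:, mask_b].sum(axis=1) - n_b * (n_b + 1) / 2
    var = n_a * n_b * (n_a + n_b + 1) / 12.0
    return np.abs(u - n_a * n_b / 2) / np.sqrt(var)


def mutual_information_scores(values: np.ndarray, y: np.ndarray, bins: int = 10) -> np.ndarray:
    _check_binary(y)
    y = np.asarray(y)
    p, n = values.shape
    idx = _bin_indices(values, bins)
    # one flat bincount for all features: cell id = feature*bins*2 + bin*2 + y
    flat = (np.arange(p)[:, None] * bins * 2 + idx * 2 + y[None, :]).ravel()
    counts = np.bincount(flat, minlength=p * bins * 2).reshape(p, bins, 2)
    out = np.empty(p)
    for i in range(p):
        out[i] = _mi_from_joint(counts[i])
    return out


def _range_scale(values: np.ndarray) -> np.ndarray:
    lo = values.min(axis=1, keepdims=True)
    rng = values.max(axis=1, keepdims=True) - lo
    rng = np.where(rng == 0, 1.0, rng)
    return (values - lo) / rng


def relieff_scores(values: np.ndarray, y: np.ndarray, k: int = 10) -> np.ndarray:
    """Binary ReliefF weights for every row of a (p, n) matrix.

    All samples serve as references (deterministic, no sampling); neighbor
    ties are broken by ascending sample index via stable sorting.
    """
    mask_a, mask_b = _check_binary(y)
    y = np.asarray(y)
    n = values.shape[1]
    counts = {0: int(mask_a.sum()), 1: int(mask_b.sum())}
    if min(counts.values()) < 2:
        raise ValueError("ReliefF needs at least 2 samples per class")
    scaled = _range_scale(values)
    # Manhattan distances between samples over all range-scaled features
    # (n x n; n is small relative to p in this domain)
    dist = np.abs(scaled[:, :, None] - scaled[:, None, :]).sum(axis=0)
    w = np.zeros(values.shape[0])
    for ref in range(n):
        same = np.flatnonzero((y == y[ref]) & (np.arange(n) != ref))
        other = np.flatnonzero(y != y[ref])
        k_hit = min(k, same.size)
        k_miss = min(k, other.size)
        hits = same[np.argsort(dist[ref, same], kind="stable")][:k_hit]
        misses = other[np.argsort(dist[ref, other], kind="stable")][:k_miss]
        hit_diff = np.abs(scaled[:, hits] - scaled[:, [ref]]).sum(axis=1) / k_hit
        miss_diff = np.abs(scaled[:, misses] - scaled[:, [ref]]).sum(axis=1) / k_miss
        w += miss_diff - hit_diff
    return w / n


def relieff_weights(
    m: ExpressionMatrix,
    design: ComparisonDesign,
    k: int = 10,
    iterations: str | int = "all_samples",
) -> FeatureScoreVector:
    """ReliefF over an expression matrix; returns raw weights in [-1, 1].

    ``iterations`` other than "all_samples" restricts references to the first
    ``iterations`` samples (kept deterministic; the default uses every
    sample, which is the stable choice for datasets of this size).
    """
    sub, y = design.restrict(m)
    values = sub.values
    if iterations != "all_samples":
        m_refs = int(iterations)
        if not 1 <= m_refs <= sub.n_samples:
            raise ValueError("iterations out of range")
        # deterministic truncation: reference set = first m_refs samples
        mask_a, mask_b = _check_binary(y)
        scaled = _range_scale(values)
        dist = np.abs(scaled[:, :, None] - scaled[:, None, :]).sum(axis=0)
        w = np.zeros(values.shape[0])
        n = values.shape[1]
        for ref in range(m_refs):
            same = np.flatnonzero((y == y[ref]) & (np.arange(n) != ref))
            other = np.flatnonzero(y != y[ref])
            if same.size == 0:
                raise ValueError("a class has a single sample")
            k_hit = min(k, same.size)
            k_miss = min(k, other.size)
            hits = same[np.argsort(dist[ref, same], kind="stable")][:k_hit]
            misses = other[np.argsort(dist[ref, other], kind="stable")][:k_miss]
            w += (np.abs(scaled[:, misses] - scaled[:, [ref]]).sum(axis=1) / k_miss
                  - np.abs(scaled[:, hits] - scaled[:, [ref]]).sum(axis=1) / k_hit)
        weights = w / m_refs
    else:
        weights = relieff_scores(values, y, k=k)
    return FeatureScoreVector(
        "relieff", dict(zip(sub.feature_ids, map(float, weights))), normalized=False
    )
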