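"""Cross-validation schemes and deterministic fold construction."""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .matrix_io import ComparisonDesign

__all__ = ["CVScheme", "make_folds", "fold_indices", "derive_seed"]


def derive_seed(master: int, *tokens) -> int:
    """Stable sub-seed from a master seed and string/int tokens (< 2**31)."""
    h = zlib.crc32(repr(tokens).encode())
    return int(np.random.SeedSequence([int(master) & 0x7FFFFFFF, h]).generate_state(1)[0] % (2**31))


@dataclass
class CVScheme:
    """kfold / holdout / leave-one-out / resubstitution validation.

    kfold and holdout are stratified by class; folds are deterministic given
    ``seed``.
    """

    kind: Literal["kfold", "holdout", "loo", "resubstitution"] = "kfold"
    k: int = 5
    holdout_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("kfold", "holdout", "loo", "resubstitution"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("kfold requires k >= 2")
        if self.kind == "holdout" and not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")

    def with_seed(self, seed: int) -> "CVScheme":
        return CVScheme(self.kind, self.k, self.holdout_fraction, seed)


def fold_indices(y: np.ndarray, scheme: CVScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, val_idx) pairs over positions of ``y`` for the scheme."""
    y = np.asarray(y)
    n = len(y)
    if scheme.kind == "resubstitution":
        idx = np.arange(n)
        return [(idx, idx.copy())]
    if scheme.kind == "loo":
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    counts = np.unique(y, return_counts=True)[1]
    if scheme.kind == "kfold":
        if counts.min() < scheme.k:
            raise ValueError(
                f"smallest class has {counts.min()} samples; cannot build {scheme.k} stratified folds"
            )
        if scheme.k > n:
            raise ValueError("k exceeds the number of samples")
        skf = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=scheme.seed)
        return [(tr, va) for tr, va in skf.split(np.zeros(n), y)]
    sss = StratifiedShuffleSplit(
        n_splits=1, test_size=scheme.holdout_fraction, random_state=scheme.seed
    )
    return [(tr, va) for tr, va in sss.split(np.zeros(n), y)]


def make_folds(design: ComparisonDesign, scheme: CVScheme) -> list[tuple[list[str], list[str]]]:
    """Stratified (train sample ids, validation sample ids) partitions."""
    samples = design.sample_ids
    y = design.labels_for(samples)
    return [
        ([samples[i] for i in tr], [samples[i] for i in va])
        for tr, va in fold_indices(y, scheme)
    ]
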