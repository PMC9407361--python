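"""Synthetic expression data with planted discriminative structure.

The generator emulates RSEM-like normalized RNA-seq expression: log-normal
non-negative values, a multiplicative (log2-scale) class effect on a planted
subset of features, many uninformative features, and sparse dropout zeros.
It provides ground truth for testing the whole selection pipeline without
any external download.

Also bundled: the clinicopathological contingency tables of a published
TCGA prostate adenocarcinoma cohort stratified into Pam50-derived molecular
subtypes (Basal / Luminal A / Luminal B), used as reference fixtures for the
association statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_stats import ContingencyTable
from .matrix_io import ComparisonDesign, ExpressionMatrix

__all__ = ["SyntheticSpec", "generate", "prostate_cohort_tables"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-feature expression model.

    value = 2 ** (log2(base_mean) + class_shift + eps), with
    eps ~ Normal(0, dispersion) per cell. Planted ("informative") features
    get class_shift = +effect/2 in one class and -effect/2 in the other, so
    the expected class difference on the log2 scale equals ``effect``.
    A ``zero_rate`` fraction of entries is then zeroed to emulate dropout.

    Defaults model a filtered immune-gene panel: 10 planted among 500
    features, 60 samples per class, a 2-fold-squared (effect = 2 log2 units)
    class shift, unit log2-scale dispersion, and 20% dropout.
    """

    n_per_class: dict[str, int] = field(default_factory=lambda: {"A": 60, "B": 60})
    n_informative: int = 10
    n_noise: int = 490
    effect: float = 2.0
    base_mean: float = 100.0
    dispersion: float = 1.0
    zero_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 2:
            raise ValueError("exactly two classes are required")
        if any(n < 2 for n in self.n_per_class.values()):
            raise ValueError("each class needs >= 2 samples")
        if self.n_informative < 0 or self.n_noise < 0 or self.n_informative + self.n_noise < 1:
            raise ValueError("feature counts must be non-negative and total >= 1")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0 <= self.zero_rate < 1:
            raise ValueError("zero_rate must be in [0, 1)")
        if self.dispersion < 0 or self.base_mean <= 0:
            raise ValueError("dispersion must be >= 0 and base_mean > 0")


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ComparisonDesign, set[str]]:
    """Draw one synthetic dataset; deterministic given ``spec.seed``.

    Returns the feature-by-sample matrix, the binary comparison design, and
    the set of planted feature ids.
    """
    rng = np.random.default_rng(spec.seed)
    (class_a, n_a), (class_b, n_b) = spec.n_per_class.items()
    n = n_a + n_b
    p = spec.n_informative + spec.n_noise
    y = np.array([0] * n_a + [1] * n_b)
    mu = np.log2(spec.base_mean)
    log2_vals = mu + rng.normal(0.0, spec.dispersion, size=(p, n))
    # planted features occupy the first rows; +effect/2 in class_a, -effect/2 in class_b
    shift = np.where(y == 0, spec.effect / 2.0, -spec.effect / 2.0)
    log2_vals[: spec.n_informative, :] += shift[None, :]
    values = np.power(2.0, log2_vals)
    if spec.zero_rate > 0:
        values[rng.uniform(size=(p, n)) < spec.zero_rate] = 0.0
    width = len(str(p))
    feature_ids = [
        (f"planted_{i:0{width}d}" if i < spec.n_informative else f"noise_{i:0{width}d}")
        for i in range(p)
    ]
    sample_ids = [f"{class_a}_{j:03d}" for j in range(n_a)] + [
        f"{class_b}_{j:03d}" for j in range(n_b)
    ]
    design = ComparisonDesign(
        {s: (class_a if y[j] == 0 else class_b) for j, s in enumerate(sample_ids)},
        class_a=class_a, class_b=class_b,
    )
    matrix = ExpressionMatrix(feature_ids, sample_ids, values)
    truth = set(feature_ids[: spec.n_informative])
    return matrix, design, truth


#: (name, row labels, counts by subtype column [Basal, LumA, LumB])
_COHORT_COUNTS = [
    ("biochemical_recurrence", ["yes", "no"],
     [[14, 3, 24], [74, 61, 120]]),
    ("radiation_therapy", ["yes", "no"],
     [[8, 6, 14], [53, 30, 85]]),
    ("radiation_follow_up", ["yes", "no"],
     [[9, 8, 25], [71, 56, 107]]),
    ("histological_type", ["acinar", "other"],
     [[101, 72, 158], [1, 0, 8]]),
    ("grade_group", ["GG1", "GG2", "GG3", "GG4+GG5"],
     [[10, 8, 11], [35, 28, 31], [17, 14, 30], [37, 21, 92]]),
    ("pathological_stage", ["pT2", "pT3+pT4"],
     [[41, 35, 50], [59, 34, 116]]),
    ("nodal_involvement", ["pN0", "pN1"],
     [[73, 52, 114], [10, 10, 37]]),
]

_SUBTYPES = ["Basal", "LumA", "LumB"]


def prostate_cohort_tables() -> list[ContingencyTable]:
    """Reference contingency tables of a TCGA prostate adenocarcinoma cohort.

    Counts of clinicopathological markers (biochemical recurrence, radiation
    therapy and follow-up, histological type, grade group, pathological
    stage, nodal involvement) across the Basal / Luminal A / Luminal B
    molecular subtypes, for exercising ``cohort_stats.chi_square_test``.
    """
    return [
        ContingencyTable(name, rows, list(_SUBTYPES), np.array(counts))
        for name, rows, counts in _COHORT_COUNTS
    ]
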