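import numpy as np
import pytest

from mfeast import ComparisonDesign, ExpressionMatrix


def make_matrix(values, feature_ids=None, sample_ids=None, non_negative=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(p)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    if non_negative is None:
        non_negative = bool(np.all(values >= 0))
    return ExpressionMatrix(feature_ids, sample_ids, values, require_non_negative=non_negative)


def make_design(y, sample_ids=None, class_a="a", class_b="b"):
    y = np.asarray(y)
    sample_ids = sample_ids or [f"s{j}" for j in range(len(y))]
    return ComparisonDesign(
        {s: (class_a if v == 0 else class_b) for s, v in zip(sample_ids, y)},
        class_a, class_b,
    )


@pytest.fixture
def four_sample_design():
    return make_design([0, 0, 1, 1])


@pytest.fixture
def planted_matrix():
    """One perfectly separating feature among standard-normal noise."""
    rng = np.random.default_rng(42)
    n = 20
    y = np.array([0] * 10 + [1] * 10)
    signal = np.where(y == 0, 0.0, 10.0) + rng.normal(0, 0.1, n)
    noise = rng.normal(size=(9, n))
    values = np.vstack([signal, noise])
    ids = ["signal"] + [f"noise{i}" for i in range(9)]
    return make_matrix(values, feature_ids=ids, non_negative=False), make_design(y), "signal"
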