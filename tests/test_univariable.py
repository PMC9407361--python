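"""Filter-scorer unit tests, including brute-force oracle equivalence.

Each oracle is an independent literal implementation of the scorer's
definition (exhaustive pair counting, joint-histogram enumeration, explicit
neighbor-update simulation), kept free of the vectorized production code
paths it checks.
"""

import numpy as np
import pytest

from mfeast import mutual_information, relieff_weights, roc_criterion, wilcoxon_criterion
from mfeast.univariable import (
    mutual_information_scores,
    relieff_scores,
    roc_scores,
    wilcoxon_scores,
)

from conftest import make_design, make_matrix


# ---------------------------------------------------------------- oracles
def oracle_auc(x, y):
    a = [v for v, c in zip(x, y) if c == 0]
    b = [v for v, c in zip(x, y) if c == 1]
    total = 0.0
    for va in a:
        for vb in b:
            if vb > va:
                total += 1.0
            elif vb == va:
                total += 0.5
    return total / (len(a) * len(b))


def oracle_roc(x, y):
    return 2 * abs(oracle_auc(x, y) - 0.5)


def oracle_wilcoxon(x, y):
    n_a = sum(1 for c in y if c == 0)
    n_b = len(y) - n_a
    u = oracle_auc(x, y) * n_a * n_b
    var = n_a * n_b * (n_a + n_b + 1) / 12.0
    return abs(u - n_a * n_b / 2) / var**0.5


def oracle_mi(x, y, bins=10):
    lo, hi = min(x), max(x)
    width = hi - lo
    joint = [[0.0] * 2 for _ in range(bins)]
    for v, c in zip(x, y):
        if width == 0:
            k = 0
        else:
            k = min(int((v - lo) / width * bins), bins - 1)
        joint[k][c] += 1
    n = len(x)
    mi = 0.0
    for k in range(bins):
        for c in range(2):
            pij = joint[k][c] / n
            if pij == 0:
                continue
            pi = sum(joint[k]) / n
            pj = sum(joint[kk][c] for kk in range(bins)) / n
            mi += pij * np.log2(pij / (pi * pj))
    return mi


def oracle_relieff(values, y, k):
    """Literal ReliefF update rule: all references, Manhattan distance,
    distance ties broken by ascending sample index."""
    p, n = values.shape
    scaled = np.empty_like(values, dtype=float)
    for f in range(p):
        lo, hi = values[f].min(), values[f].max()
        scaled[f] = 0.0 if hi == lo else (values[f] - lo) / (hi - lo)
    w = [0.0] * p
    for ref in range(n):
        dists = []
        for other in range(n):
            if other == ref:
                continue
            d = sum(abs(scaled[f, ref] - scaled[f, other]) for f in range(p))
            dists.append((d, other))
        dists.sort()
        hits = [o for _, o in dists if y[o] == y[ref]][:k]
        misses = [o for _, o in dists if y[o] != y[ref]][:k]
        k_hit, k_miss = len(hits), len(misses)
        for f in range(p):
            w[f] += sum(abs(scaled[f, ref] - scaled[f, o]) for o in misses) / k_miss
            w[f] -= sum(abs(scaled[f, ref] - scaled[f, o]) for o in hits) / k_hit
    return [v / n for v in w]


def random_instances(n_instances=50, seed=2024):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_instances:
        n = int(rng.integers(4, 13))
        p = int(rng.integers(1, 5))
        n_a = int(rng.integers(2, n - 1))
        if n - n_a < 2:
            continue
        y = np.array([0] * n_a + [1] * (n - n_a))
        rng.shuffle(y)
        # half the instances get heavy ties via integer values
        if rng.uniform() < 0.5:
            values = rng.integers(0, 4, size=(p, n)).astype(float)
        else:
            values = rng.normal(size=(p, n))
        out.append((values, y))
    return out


INSTANCES = random_instances()


class TestOracleEquivalence:
    @pytest.mark.parametrize("case", range(len(INSTANCES)))
    def test_scalar_scorers_match_bruteforce(self, case):
        values, y = INSTANCES[case]
        for x in values:
            assert roc_criterion(x, y) == pytest.approx(oracle_roc(x, y), abs=1e-10)
            assert wilcoxon_criterion(x, y) == pytest.approx(oracle_wilcoxon(x, y), abs=1e-10)
            assert mutual_information(x, y) == pytest.approx(oracle_mi(x, y), abs=1e-10)

    @pytest.mark.parametrize("case", range(0, len(INSTANCES), 2))
    def test_relieff_matches_literal_update_rule(self, case):
        values, y = INSTANCES[case]
        k = min(3, np.bincount(y).min() - 1) or 1
        got = relieff_scores(values, y, k=k)
        want = oracle_relieff(values, y, k)
        np.testing.assert_allclose(got, want, atol=1e-10)

    @pytest.mark.parametrize("case", range(0, len(INSTANCES), 5))
    def test_vectorized_rows_match_scalar(self, case):
        values, y = INSTANCES[case]
        np.testing.assert_allclose(
            roc_scores(values, y), [roc_criterion(x, y) for x in values], atol=1e-12
        )
        np.testing.assert_allclose(
            wilcoxon_scores(values, y), [wilcoxon_criterion(x, y) for x in values],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            mutual_information_scores(values, y),
            [mutual_information(x, y) for x in values], atol=1e-12,
        )


class TestRocCriterion:
    def test_perfect_separation(self):
        assert roc_criterion([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_constant_feature_scores_zero(self):
        assert roc_criterion([3, 3, 3, 3], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_partial_overlap_half(self):
        assert roc_criterion([1, 3, 2, 4], [0, 0, 1, 1]) == pytest.approx(0.5)

    def test_label_swap_and_negation_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = np.array([0] * 5 + [1] * 5)
        s = roc_criterion(x, y)
        assert roc_criterion(x, 1 - y) == pytest.approx(s)
        assert roc_criterion(-x, y) == pytest.approx(s)

    def test_one_class_absent_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_criterion([1, 2], [0, 0])


class TestWilcoxonCriterion:
    def test_exact_rank_sum_example(self):
        # U = 3, mean 2, var 5/3
        assert wilcoxon_criterion([1, 3, 2, 4], [0, 0, 1, 1]) == pytest.approx(
            1 / np.sqrt(5 / 3)
        )

    def test_all_ties_scores_zero(self):
        assert wilcoxon_criterion([7, 7, 7, 7], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        y = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        assert wilcoxon_criterion(x, 1 - y) == pytest.approx(wilcoxon_criterion(x, y))


class TestMutualInformation:
    def test_class_indicator_is_one_bit(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_constant_feature_zero_bits(self):
        assert mutual_information([2, 2, 2, 2], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_2x2_joint_table_example(self):
        want = 2 * ((1 / 3) * np.log2(4 / 3) + (1 / 6) * np.log2(2 / 3))
        assert mutual_information([0, 0, 1, 1, 0, 1], [0, 0, 0, 1, 1, 1]) == pytest.approx(want)

    def test_non_negative(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.integers(0, 2, size=12)
            if len(set(y)) < 2:
                continue
            assert mutual_information(x, y) >= 0


class TestRelieff:
    def test_single_perfect_feature(self, four_sample_design):
        m = make_matrix([[0, 0, 1, 1]])
        res = relieff_weights(m, four_sample_design, k=1)
        assert res.scores["f0"] == pytest.approx(1.0)

    def test_constant_feature_weight_zero(self, four_sample_design):
        m = make_matrix([[0, 0, 1, 1], [5, 5, 5, 5]])
        res = relieff_weights(m, four_sample_design, k=1)
        assert res.scores["f1"] == pytest.approx(0.0)

    def test_sample_duplication_invariance(self):
        values = np.array([[0.0, 0.0, 1.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        base = relieff_scores(values, y, k=1)
        doubled = relieff_scores(np.tile(values, 2), np.tile(y, 2), k=2)
        np.testing.assert_allclose(doubled, base, atol=1e-12)

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(5, 12))
        y = np.array([0] * 6 + [1] * 6)
        w = relieff_scores(values, y, k=3)
        assert np.all(w >= -1 - 1e-12) and np.all(w <= 1 + 1e-12)

    def test_disjoint_supports_positive_weight(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 6 + [1] * 6)
        values = np.vstack([
            np.where(y == 0, rng.uniform(0, 1, 12), rng.uniform(2, 3, 12)),
            rng.normal(size=(3, 12)),
        ])
        w = relieff_scores(values, y, k=3)
        assert w[0] > 0
        assert roc_scores(values, y)[0] == pytest.approx(1.0)


class TestPermutationInvariance:
    def test_all_scorers_invariant_to_sample_order(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(3, 10))
        y = np.array([0] * 5 + [1] * 5)
        perm = rng.permutation(10)
        for fn in (roc_scores, wilcoxon_scores, mutual_information_scores):
            np.testing.assert_allclose(
                fn(values, y), fn(values[:, perm], y[perm]), atol=1e-12
            )
        np.testing.assert_allclose(
            relieff_scores(values, y, k=2),
            relieff_scores(values[:, perm], y[perm], k=2), atol=1e-12,
        )

    def test_rank_scorers_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=12)
        y = np.array([0] * 6 + [1] * 6)
        for g in (np.exp, lambda v: v**3, lambda v: 2 * v + 7):
            assert roc_criterion(g(x), y) == pytest.approx(roc_criterion(x, y))
            assert wilcoxon_criterion(g(x), y) == pytest.approx(wilcoxon_criterion(x, y))
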