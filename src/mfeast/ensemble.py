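"""Ensemble orchestration: run all selected scorers under cross-validation and
combine them into a single 0-1 ranking by a greedy ensemble vote.

Aggregation model
-----------------
Raw-score methods (the four univariable filters and the four tree-ensemble
importance methods) run once per CV fold on that fold's *training* samples.
Within each fold the raw scores are min-max normalized over features (an
all-equal score vector normalizes to all zeros), then averaged across folds,
giving a per-method score in [0, 1] for every feature.

The four sequential wrappers instead use the CV scheme as the internal
selection criterion of the forward search, repeated ``iterations`` times with
re-randomized partitions; a feature's method score is the fraction of repeats
that selected it (0, 1/5, ..., 1 at the default five repeats).

The ensemble score of a feature is the mean of its per-method scores. The
final ranking is built greedily: repeatedly extract the remaining feature
with the largest ensemble score, breaking ties in favor of the feature with
the better (smaller) mean rank position across methods, then
lexicographically by feature id. The result is a score in [0, 1] per feature
(1 = perfect discriminator by unanimous vote) and a rank permutation 1..p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .cv import CVScheme, derive_seed, fold_indices, make_folds  # noqa: F401 (re-export)
from .matrix_io import ComparisonDesign, ExpressionMatrix
from .multivariable import (
    boosted_tree_importance,
    forest_permutation_importance,
    membership_scores,
    sequential_forward_select,
)
from .univariable import (
    mutual_information_scores,
    relieff_scores,
    roc_scores,
    wilcoxon_scores,
)

__all__ = [
    "CVScheme",
    "make_folds",
    "MethodScoreTable",
    "EnsembleRanking",
    "ALL_METHODS",
    "run_ensemble",
    "aggregate_scores",
    "select_features",
]

#: raw-score methods evaluated per fold (filter + embedded)
FOLD_SCORERS: dict[str, Callable] = {
    "mutinf": lambda vals, y, seed: mutual_information_scores(vals, y),
    "roc": lambda vals, y, seed: roc_scores(vals, y),
    "wilcoxon": lambda vals, y, seed: wilcoxon_scores(vals, y),
    "relieff": lambda vals, y, seed: relieff_scores(vals, y),
}

WRAPPER_METHODS = {"svm_sfs": "linear_svm", "knn_sfs": "knn", "tree_sfs": "tree", "qda_sfs": "qda"}
IMPORTANCE_METHODS = ("treebagger", "bag", "gentleboost", "rusboost")

ALL_METHODS = (
    "mutinf", "roc", "wilcoxon", "relieff",
    "svm_sfs", "knn_sfs", "tree_sfs", "qda_sfs",
    "treebagger", "bag", "gentleboost", "rusboost",
)


@dataclass
class MethodScoreTable:
    """Per-(method, fold) raw scores and per-method fold-averaged normalized scores."""

    raw: dict[tuple[str, int], dict[str, float]] = field(default_factory=dict)
    method_scores: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class EnsembleRanking:
    ensemble_score: dict[str, float]
    rank: dict[str, int]
    method_table: MethodScoreTable
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = len(self.ensemble_score)
        if sorted(self.rank.values()) != list(range(1, p + 1)):
            raise ValueError("ranks must be a permutation of 1..p")
        order = sorted(self.rank, key=self.rank.get)
        scores = [self.ensemble_score[f] for f in order]
        if any(scores[i] < scores[i + 1] - 1e-12 for i in range(len(scores) - 1)):
            raise ValueError("ensemble_score must be non-increasing along rank order")

    def ordered_features(self) -> list[str]:
        return sorted(self.rank, key=self.rank.get)


def _minmax(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def aggregate_scores(
    method_scores: dict[str, dict[str, float]],
) -> tuple[dict[str, float], dict[str, int]]:
    """Greedy ensemble vote over per-method normalized scores.

    ``method_scores`` maps method -> feature -> score in [0, 1]. The
    ensemble score of a feature is the mean over methods; features are
    extracted greedily by descending ensemble score, ties going to the
    feature with the better (smaller) mean per-method rank position, then
    lexicographic id. Returns (ensemble_score, rank).
    """
    if not method_scores:
        raise ValueError("no method scores to aggregate")
    feature_ids = list(next(iter(method_scores.values())))
    for meth, scores in method_scores.items():
        if set(scores) != set(feature_ids):
            raise ValueError(f"method {meth!r} scores a different feature set")
    matrix = np.array(
        [[scores[f] for f in feature_ids] for scores in method_scores.values()]
    )
    ensemble = matrix.mean(axis=0)
    rank_positions = rankdata(-matrix, axis=1, method="average").mean(axis=0)
    order = sorted(
        range(len(feature_ids)),
        key=lambda i: (-ensemble[i], rank_positions[i], feature_ids[i]),
    )
    rank = {feature_ids[i]: r for r, i in enumerate(order, start=1)}
    return dict(zip(feature_ids, map(float, ensemble))), rank


def run_ensemble(
    m: ExpressionMatrix,
    design: ComparisonDesign,
    methods: Sequence[str] | str = "all",
    scheme: CVScheme | None = None,
    iterations: int = 5,
    seed: int = 0,
    max_features: int | None = None,
    skip_failing: bool = False,
    extra_scorers: dict[str, Callable] | None = None,
    warn: Callable[[str], None] | None = None,
) -> EnsembleRanking:
    """Score every feature with the selected methods and aggregate greedily.

    Parameters
    ----------
    methods : "all" or list of method names from ``ALL_METHODS``.
    scheme : cross-validation scheme (default stratified 5-fold).
    iterations : repeats of each sequential forward search.
    seed : master seed; every stochastic sub-procedure derives its own
        stream from (seed, method name, repeat/fold index).
    extra_scorers : optional extra raw fold-scorers, mapping name ->
        f(values, y, seed) -> per-feature score array (used e.g. to test
        aggregation invariances).
    skip_failing : drop a method that raises instead of aborting.
    """
    if scheme is None:
        scheme = CVScheme("kfold", k=5, seed=seed)
    if methods == "all":
        methods = list(ALL_METHODS)
    methods = list(methods)
    if not methods:
        raise ValueError("at least one method is required")
    fold_scorers = dict(FOLD_SCORERS)
    if extra_scorers:
        fold_scorers.update(extra_scorers)
    known = set(fold_scorers) | set(WRAPPER_METHODS) | set(IMPORTANCE_METHODS)
    unknown = [meth for meth in methods if meth not in known]
    if unknown:
        raise ValueError(f"unknown methods: {', '.join(unknown)}")

    sub, y = design.restrict(m)
    feature_ids = sub.feature_ids
    p = len(feature_ids)
    folds = fold_indices(y, scheme.with_seed(derive_seed(seed, "folds")))

    table = MethodScoreTable()
    failed: list[str] = []
    for meth in methods:
        try:
            if meth in fold_scorers or meth in IMPORTANCE_METHODS:
                per_fold = []
                for fold_i, (tr, _va) in enumerate(folds):
                    fold_seed = derive_seed(seed, meth, fold_i)
                    try:
                        if meth in fold_scorers:
                            raw = np.asarray(
                                fold_scorers[meth](sub.values[:, tr], y[tr], fold_seed),
                                dtype=float,
                            )
                        else:
                            train_m = sub.subset_samples([sub.sample_ids[i] for i in tr])
                            if meth == "treebagger":
                                res = forest_permutation_importance(
                                    train_m, design, seed=fold_seed
                                )
                            else:
                                variant = "bagging" if meth == "bag" else meth
                                res = boosted_tree_importance(
                                    train_m, design, variant=variant, seed=fold_seed
                                )
                            raw = np.array([res.importances[f] for f in feature_ids])
                    except Exception as exc:
                        raise RuntimeError(f"method {meth!r} failed on fold {fold_i}: {exc}") from exc
                    table.raw[(meth, fold_i)] = dict(zip(feature_ids, map(float, raw)))
                    per_fold.append(_minmax(raw))
                avg = np.mean(per_fold, axis=0)
            else:  # sequential wrapper: CV scheme is the internal criterion
                results = sequential_forward_select(
                    sub, design, WRAPPER_METHODS[meth], scheme,
                    max_features=max_features, n_repeats=iterations,
                    seed=derive_seed(seed, meth),
                )
                for rep_i, res in enumerate(results):
                    table.raw[(meth, rep_i)] = {
                        f: (1.0 if f in res.selected else 0.0) for f in feature_ids
                    }
                votes = membership_scores(results, feature_ids)
                avg = np.array([votes[f] for f in feature_ids])
            table.method_scores[meth] = dict(zip(feature_ids, map(float, avg)))
        except Exception:
            if not skip_failing:
                raise
            failed.append(meth)
            if warn is not None:
                warn(f"dropping failing method {meth!r}")
    kept = [meth for meth in methods if meth not in failed]
    if not kept:
        raise RuntimeError("every method failed")

    ensemble, rank = aggregate_scores(
        {meth: table.method_scores[meth] for meth in kept}
    )
    config = {
        "methods": kept,
        "dropped": failed,
        "cv": {"kind": scheme.kind, "k": scheme.k,
               "holdout_fraction": scheme.holdout_fraction},
        "iterations": iterations,
        "seed": seed,
        "n_features": p,
        "n_samples": sub.n_samples,
        "comparison": [design.class_a, design.class_b],
    }
    return EnsembleRanking(ensemble, rank, table, config)


def select_features(r: EnsembleRanking, mode: str = "all", arg=None) -> list[str]:
    """Final feature selection: everything, a top fraction, or a custom list.

    ``top_fraction`` keeps the first ``ceil(arg * p)`` features in rank
    order; ``custom`` reorders the given ids by rank.
    """
    ordered = r.ordered_features()
    if mode == "all":
        return ordered
    if mode == "top_fraction":
        if arg is None or not 0 < arg <= 1:
            raise ValueError("top_fraction requires arg in (0, 1]")
        return ordered[: math.ceil(arg * len(ordered))]
    if mode == "custom":
        wanted = set(arg or [])
        unknown = sorted(wanted - set(ordered))
        if unknown:
            raise ValueError(f"unknown feature ids: {', '.join(unknown)}")
        return [f for f in ordered if f in wanted]
    raise ValueError(f"unknown selection mode {mode!r}")
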