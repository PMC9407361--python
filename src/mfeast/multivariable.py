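"""Wrapper- and embedded-type feature scorers.

Wrappers run a greedy sequential forward search: starting from the empty set,
repeatedly add the feature whose inclusion minimizes the mean cross-validated
misclassification rate of a base learner (linear SVM, k-NN, decision tree, or
QDA), stopping when no candidate strictly improves the criterion. The search
is repeated with re-randomized CV partitions and each repeat's selected set
contributes a binary membership vote.

Embedded methods derive importances from tree ensembles: out-of-bag
permutation importance of bagged trees ("treebagger"), and split-gain
importances under plain bagging, GentleBoost, and RUSBoost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sklearn
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .cv import CVScheme, derive_seed, fold_indices
from .matrix_io import ComparisonDesign, ExpressionMatrix

__all__ = [
    "WrapperResult",
    "ImportanceResult",
    "sequential_forward_select",
    "forest_permutation_importance",
    "boosted_tree_importance",
    "WRAPPER_LEARNERS",
]

WRAPPER_LEARNERS = ("linear_svm", "knn", "tree", "qda")


@dataclass
class WrapperResult:
    method: str
    selected: set[str]
    criterion_trace: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for fid, rate in self.criterion_trace:
            if not 0 <= rate <= 1:
                raise ValueError(f"criterion rate {rate} for {fid!r} outside [0, 1]")


@dataclass
class ImportanceResult:
    method: str
    importances: dict[str, float]
    n_learners: int
    seed: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.importances.values()):
            raise ValueError("importances must be >= 0")


class _SubsetEvaluator:
    """Mean CV misclassification of one learner over a growing feature subset.

    ``error(cols, cand)`` evaluates the subset ``cols + [cand]``; ``commit(f)``
    notifies the evaluator that ``f`` was adopted (used to cache incremental
    state). A fold where the learner cannot fit contributes the worst
    possible rate, 1.0.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, folds, seed: int):
        self.X, self.y, self.folds, self.seed = X, y, folds, seed

    def error(self, cols: list[int], cand: int) -> float:
        raise NotImplementedError

    def commit(self, f: int) -> None:
        pass


class _SklearnEvaluator(_SubsetEvaluator):
    def _fit_predict(self, Xtr, ytr, Xva):
        raise NotImplementedError

    def error(self, cols, cand):
        use = cols + [cand]
        errs = []
        for tr, va in self.folds:
            try:
                pred = self._fit_predict(self.X[np.ix_(tr, use)], self.y[tr],
                                         self.X[np.ix_(va, use)])
                errs.append(float(np.mean(pred != self.y[va])))
            except Exception:
                errs.append(1.0)
        return float(np.mean(errs))


class _SvmEvaluator(_SklearnEvaluator):
    def _fit_predict(self, Xtr, ytr, Xva):
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(Xtr, ytr)
        return clf.predict(Xva)


class _TreeEvaluator(_SklearnEvaluator):
    """Gini decision tree; inputs pre-cast to float32 to skip re-validation."""

    def __init__(self, X, y, folds, seed):
        super().__init__(np.ascontiguousarray(X, dtype=np.float32), y, folds, seed)

    def _fit_predict(self, Xtr, ytr, Xva):
        tree = DecisionTreeClassifier(criterion="gini", random_state=self.seed)
        tree.fit(np.ascontiguousarray(Xtr), ytr, check_input=False)
        return tree.predict(np.ascontiguousarray(Xva), check_input=False)


class _KnnEvaluator(_SubsetEvaluator):
    """k-NN (k = 5, Euclidean, majority vote) with incremental distances.

    Squared distances over the already-selected subset are cached per fold,
    so evaluating a candidate adds a single per-feature squared-difference
    term. Vote ties (possible only when k is clipped to an even training
    size) deterministically predict class 0.
    """

    k = 5

    def __init__(self, X, y, folds, seed):
        super().__init__(X, y, folds, seed)
        self.state = [
            {"tr": tr, "va": va,
             "d": np.zeros((len(va), len(tr))),
             "ytr": y[tr], "yva": y[va]}
            for tr, va in folds
        ]

    def _sqdiff(self, st, f):
        return (self.X[st["va"], f][:, None] - self.X[st["tr"], f][None, :]) ** 2

    def error(self, cols, cand):
        errs = []
        for st in self.state:
            d = st["d"] + self._sqdiff(st, cand)
            k = min(self.k, d.shape[1])
            if k < d.shape[1]:
                near = np.argpartition(d, k - 1, axis=1)[:, :k]
            else:
                near = np.broadcast_to(np.arange(d.shape[1]), d.shape)
            votes = st["ytr"][near].sum(axis=1)
            pred = (2 * votes > k).astype(int)
            errs.append(float(np.mean(pred != st["yva"])))
        return float(np.mean(errs))

    def commit(self, f):
        for st in self.state:
            st["d"] += self._sqdiff(st, f)


class _QdaEvaluator(_SubsetEvaluator):
    """Quadratic discriminant with a 1e-6 ridge on each class covariance.

    Class means and centered training blocks are precomputed per fold, so a
    candidate subset's covariance is a small Gram product. A singular
    (non-positive-definite) covariance makes the fold score 1.0.
    """

    ridge = 1e-6

    def __init__(self, X, y, folds, seed):
        super().__init__(X, y, folds, seed)
        self.state = []
        for tr, va in folds:
            classes = []
            for c in (0, 1):
                idx = tr[y[tr] == c]
                mu = X[idx].mean(axis=0)
                classes.append({
                    "mu": mu, "centered": X[idx] - mu, "n": len(idx),
                    "logprior": np.log(len(idx) / len(tr)),
                })
            self.state.append({"va": va, "yva": y[va], "classes": classes})

    def error(self, cols, cand):
        use = cols + [cand]
        errs = []
        for st in self.state:
            Xva = self.X[np.ix_(st["va"], use)]
            scores = np.empty((len(st["va"]), 2))
            ok = True
            for c, cl in enumerate(st["classes"]):
                if cl["n"] < 2:
                    ok = False
                    break
                Z = cl["centered"][:, use]
                cov = Z.T @ Z / (cl["n"] - 1) + self.ridge * np.eye(len(use))
                try:
                    L = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    ok = False
                    break
                diff = Xva - cl["mu"][use]
                w = np.linalg.solve(L, diff.T)
                maha = np.sum(w**2, axis=0)
                logdet = 2 * np.sum(np.log(np.diag(L)))
                scores[:, c] = -0.5 * (maha + logdet) + cl["logprior"]
            if not ok:
                errs.append(1.0)
                continue
            pred = scores.argmax(axis=1)
            errs.append(float(np.mean(pred != st["yva"])))
        return float(np.mean(errs))


_EVALUATORS = {
    "linear_svm": _SvmEvaluator,
    "knn": _KnnEvaluator,
    "tree": _TreeEvaluator,
    "qda": _QdaEvaluator,
}


def sequential_forward_select(
    m: ExpressionMatrix,
    design: ComparisonDesign,
    learner: str,
    cv: CVScheme,
    max_features: int | None = None,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[WrapperResult]:
    """Greedy forward selection, repeated over re-randomized CV partitions.

    Each repeat draws a fresh stratified partition (seeded from
    ``seed`` + repeat index), then grows the subset while the mean CV
    misclassification strictly decreases. The empty-set baseline is the
    majority-class error, so a repeat can return an empty set when no single
    feature beats always-predicting the majority class. Candidate ties take
    the earliest feature in matrix order.
    """
    if learner not in WRAPPER_LEARNERS:
        raise ValueError(f"unknown wrapper learner {learner!r}")
    sub, y = design.restrict(m)
    p = sub.n_features
    if p < 1:
        raise ValueError("no features to select from")
    budget = min(max_features if max_features is not None else 50, p)
    if budget < 1:
        raise ValueError("max_features must be >= 1")
    X_full = np.ascontiguousarray(sub.values.T)  # samples x features
    results = []
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for rep in range(n_repeats):
            rep_seed = derive_seed(seed, "sfs", learner, rep)
            folds = fold_indices(y, cv.with_seed(rep_seed))
            evaluator = _EVALUATORS[learner](X_full, y, folds, rep_seed)
            baseline = float(np.mean(y != (np.bincount(y).argmax())))
            selected_idx: list[int] = []
            trace: list[tuple[str, float]] = []
            current_err = baseline
            remaining = list(range(p))
            while remaining and len(selected_idx) < budget:
                best_f, best_err = None, None
                for f in remaining:
                    err = evaluator.error(selected_idx, f)
                    if best_err is None or err < best_err:
                        best_f, best_err = f, err
                if best_err is None or best_err >= current_err:
                    break
                selected_idx.append(best_f)
                remaining.remove(best_f)
                evaluator.commit(best_f)
                trace.append((sub.feature_ids[best_f], best_err))
                current_err = best_err
            results.append(
                WrapperResult(f"{learner}_sfs", {sub.feature_ids[i] for i in selected_idx}, trace)
            )
    return results


def membership_scores(results: list[WrapperResult], feature_ids: list[str]) -> dict[str, float]:
    """Fraction of repeats in which each feature was selected."""
    out = {f: 0.0 for f in feature_ids}
    for res in results:
        for f in res.selected:
            out[f] += 1.0 / len(results)
    return out


def forest_permutation_importance(
    m: ExpressionMatrix,
    design: ComparisonDesign,
    n_trees: int = 100,
    seed: int = 0,
) -> ImportanceResult:
    """Out-of-bag permutation importance of a bagged-tree ensemble.

    Per tree (bootstrap sample, sqrt(p) features per split): the increase in
    out-of-bag error when one feature's OOB values are permuted. The
    importance is the per-tree mean increase divided by its standard
    deviation over trees (0 when the deviation is 0); negatives clip to 0.
    Features a tree never splits on contribute an exact zero for that tree.
    """
    if n_trees < 10:
        raise ValueError("n_trees must be >= 10")
    sub, y = design.restrict(m)
    X = np.ascontiguousarray(sub.values.T)
    n, p = X.shape
    rng = np.random.default_rng(derive_seed(seed, "treebagger"))
    deltas = np.zeros((n_trees, p))
    valid = np.zeros(n_trees, dtype=bool)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            criterion="gini", max_features="sqrt",
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X[boot], y[boot])
        valid[t] = True
        base_err = np.mean(tree.predict(X[oob]) != y[oob])
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if used.size == 0:
            continue
        # one batched predict over all permuted copies of this tree's features
        X_oob = X[oob]
        stacked = np.repeat(X_oob[None, :, :], used.size, axis=0)
        for i, f in enumerate(used):
            stacked[i, :, f] = X_oob[rng.permutation(oob.size), f]
        preds = tree.predict(stacked.reshape(-1, p)).reshape(used.size, oob.size)
        deltas[t, used] = np.mean(preds != y[oob][None, :], axis=1) - base_err
    if not valid.any():
        raise RuntimeError("no valid bootstrap replicate produced both classes")
    d = deltas[valid]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1) if d.shape[0] > 1 else np.zeros(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        imp = np.where(sd > 0, mean / np.where(sd == 0, 1, sd), 0.0)
    imp = np.clip(imp, 0.0, None)
    return ImportanceResult(
        "treebagger", dict(zip(sub.feature_ids, map(float, imp))), int(valid.sum()), seed
    )


def _accumulate_gain(tree, p: int) -> np.ndarray:
    """Weighted impurity decrease per feature (unnormalized split gains)."""
    return tree.tree_.compute_feature_importances(normalize=False) * tree.tree_.weighted_n_node_samples[0]


def boosted_tree_importance(
    m: ExpressionMatrix,
    design: ComparisonDesign,
    variant: str = "bagging",
    n_learners: int = 100,
    max_depth: int | None = None,
    seed: int = 0,
) -> ImportanceResult:
    """Split-gain importances from bagging / GentleBoost / RUSBoost ensembles.

    * bagging — bootstrap-resampled full-depth Gini trees.
    * gentleboost — stage-wise additive regression stumps fit by weighted
      least squares to the +/-1 response, weight update
      w <- w * exp(-y * f_t(x)), renormalized each round.
    * rusboost — AdaBoost-style rounds where each learner trains on the
      minority class plus a 1:1 without-replacement undersample of the
      majority class; a round with weighted error >= 0.5 is resampled up to
      10 times before stopping early.

    Importance of a feature is the sample-weighted Gini (or variance, for the
    regression stumps) decrease summed over every split on it across all
    learners.
    """
    if variant not in ("bagging", "gentleboost", "rusboost"):
        raise ValueError(f"unknown variant {variant!r}")
    sub, y01 = design.restrict(m)
    X = np.ascontiguousarray(sub.values.T)
    n, p = X.shape
    rng = np.random.default_rng(derive_seed(seed, "boost", variant))
    gains = np.zeros(p)
    n_fitted = 0
    if variant == "bagging":
        depth = max_depth
        for _ in range(n_learners):
            boot = rng.integers(0, n, size=n)
            if len(np.unique(y01[boot])) < 2:
                continue
            tree = DecisionTreeClassifier(
                criterion="gini", max_depth=depth,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[boot], y01[boot])
            gains += _accumulate_gain(tree, p)
            n_fitted += 1
    elif variant == "gentleboost":
        depth = 1 if max_depth is None else max_depth
        y = np.where(y01 == 1, 1.0, -1.0)
        w = np.full(n, 1.0 / n)
        for _ in range(n_learners):
            stump = DecisionTreeRegressor(
                max_depth=depth, random_state=int(rng.integers(2**31))
            )
            stump.fit(X, y, sample_weight=w)
            f_t = stump.predict(X)
            gains += _accumulate_gain(stump, p)
            n_fitted += 1
            w = w * np.exp(-y * f_t)
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                break
            w /= total
    else:  # rusboost
        if len(np.unique(y01)) < 2:
            raise ValueError("RUSBoost requires both classes")
        depth = 3 if max_depth is None else max_depth
        w = np.full(n, 1.0 / n)
        idx_a, idx_b = np.flatnonzero(y01 == 0), np.flatnonzero(y01 == 1)
        minority, majority = (idx_a, idx_b) if idx_a.size <= idx_b.size else (idx_b, idx_a)
        for _ in range(n_learners):
            for _attempt in range(10):
                keep_maj = rng.choice(majority, size=minority.size, replace=False)
                train = np.concatenate([minority, keep_maj])
                tree = DecisionTreeClassifier(
                    criterion="gini", max_depth=depth,
                    random_state=int(rng.integers(2**31)),
                )
                tree.fit(X[train], y01[train], sample_weight=w[train])
                pred = tree.predict(X)
                err = float(np.sum(w * (pred != y01)))
                if err < 0.5:
                    break
            else:
                break  # 10 degenerate resamples: stop with the learners so far
            gains += _accumulate_gain(tree, p)
            n_fitted += 1
            err = max(err, 1e-10)
            alpha = 0.5 * np.log((1 - err) / err)
            w = w * np.exp(alpha * (pred != y01))
            w /= w.sum()
    if n_fitted == 0:
        raise RuntimeError(f"{variant}: no learner could be fitted")
    return ImportanceResult(
        variant, dict(zip(sub.feature_ids, map(float, np.clip(gains, 0, None)))), n_fitted, seed
    )
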