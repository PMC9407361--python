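"""Downstream assessment of a selected biomarker panel.

``classify_panel`` measures how well a feature panel separates the two
classes with a linear SVM under stratified cross-validation;
``cluster_samples`` reproduces the heatmap-style unsupervised view
(average-linkage agglomeration on 1 - Spearman correlation between samples);
``embed_samples`` provides a seeded 2-D t-SNE layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.manifold import TSNE
from sklearn.svm import SVC

from .cv import CVScheme, derive_seed, fold_indices
from .matrix_io import ComparisonDesign, ExpressionMatrix

__all__ = ["ClassifierReport", "ClusterResult", "classify_panel", "cluster_samples",
           "embed_samples", "confusion_metrics"]


@dataclass
class ClassifierReport:
    """Fold-wise accuracy / precision / recall / F1 with mean and sd.

    ``positive_class`` is the class treated as "positive" in the
    precision/recall sense (the comparison's first class).
    """

    accuracy: list[float]
    precision: list[float]
    recall: list[float]
    f1: list[float]
    positive_class: str

    def __post_init__(self) -> None:
        for name in ("accuracy", "precision", "recall", "f1"):
            vals = getattr(self, name)
            if any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"{name} values outside [0, 1]")

    @property
    def n_folds(self) -> int:
        return len(self.accuracy)

    def summary(self) -> dict[str, tuple[float, float]]:
        """metric -> (mean, sd) over folds (sd with the n-1 convention)."""
        out = {}
        for name in ("accuracy", "precision", "recall", "f1"):
            vals = np.array(getattr(self, name))
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out[name] = (float(vals.mean()), sd)
        return out


@dataclass
class ClusterResult:
    merges: list[tuple[int, int, float]]
    sample_order: list[str]
    distance_matrix: np.ndarray


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy, precision, recall, F1 from one fold's confusion counts.

    F1 is defined as 0 when precision + recall = 0.
    """
    n = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"accuracy": (tp + tn) / n, "precision": precision, "recall": recall, "f1": f1}


def classify_panel(
    m: ExpressionMatrix,
    design: ComparisonDesign,
    folds: int = 10,
    seed: int = 0,
) -> ClassifierReport:
    """Linear-SVM (C = 1) cross-validated classification of a feature panel.

    Features are z-scored with training-fold statistics only; each stratified
    fold is evaluated on its held-out samples. Metrics are macro-averaged
    over folds by the caller via ``ClassifierReport.summary``.
    """
    if m.n_features == 0:
        raise ValueError("panel is empty")
    sub, y = design.restrict(m)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} samples for {folds}-fold stratified CV"
        )
    X = sub.values.T
    scheme = CVScheme("kfold", k=folds, seed=derive_seed(seed, "classify"))
    acc, prec, rec, f1s = [], [], [], []
    for tr, va in fold_indices(y, scheme):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        clf = SVC(kernel="linear", C=1.0)
        clf.fit((X[tr] - mu) / sd, y[tr])
        pred = clf.predict((X[va] - mu) / sd)
        truth = y[va]
        # positive class = class_a, encoded 0
        tp = int(np.sum((pred == 0) & (truth == 0)))
        fp = int(np.sum((pred == 0) & (truth == 1)))
        fn = int(np.sum((pred == 1) & (truth == 0)))
        tn = int(np.sum((pred == 1) & (truth == 1)))
        met = confusion_metrics(tp, fp, fn, tn)
        acc.append(met["accuracy"])
        prec.append(met["precision"])
        rec.append(met["recall"])
        f1s.append(met["f1"])
    return ClassifierReport(acc, prec, rec, f1s, positive_class=design.class_a)


def spearman_distance_matrix(m: ExpressionMatrix) -> np.ndarray:
    """1 - Spearman correlation between sample columns over the panel."""
    ranks = rankdata(m.values, axis=0)  # rank each sample's profile over features
    sd = ranks.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"sample {m.sample_ids[flat[0]]!r} has zero variance across the panel; "
            "Spearman correlation is undefined"
        )
    rho = np.corrcoef(ranks.T)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def upgma_merges(dist: np.ndarray, sample_ids: list[str]) -> ClusterResult:
    """Unweighted average-linkage agglomeration of a precomputed distance matrix."""
    Z = linkage(squareform(dist, checks=False), method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    order = [sample_ids[i] for i in leaves_list(Z)]
    return ClusterResult(merges, order, dist)


def cluster_samples(
    m: ExpressionMatrix,
    linkage_method: str = "average",
    similarity: str = "spearman",
) -> ClusterResult:
    """UPGMA clustering of samples under Spearman-correlation distance."""
    if linkage_method != "average":
        raise ValueError("only average linkage (UPGMA) is supported")
    if similarity != "spearman":
        raise ValueError("only Spearman similarity is supported")
    if m.n_samples < 2 or m.n_features < 2:
        raise ValueError("need >= 2 samples and >= 2 panel features")
    dist = spearman_distance_matrix(m)
    return upgma_merges(dist, m.sample_ids)


def embed_samples(m: ExpressionMatrix, method: str = "tsne", seed: int = 0) -> np.ndarray:
    """2-D t-SNE coordinates of samples (rows follow ``m.sample_ids``)."""
    if method != "tsne":
        raise ValueError("only t-SNE embedding is supported")
    n = m.n_samples
    if n < 5:
        raise ValueError("need >= 5 samples for an embedding")
    perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=derive_seed(seed, "tsne"),
        init="pca",
    )
    return tsne.fit_transform(m.values.T)
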