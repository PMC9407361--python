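"""Reading and writing expression matrices, label files, clinical tables and rankings.

All file formats are plain delimited text. The canonical in-memory orientation
is features x samples ("feature matrix"): one row per molecular feature, one
column per sample.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ComparisonDesign",
    "ClinicalTable",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "read_clinical",
    "write_ranking",
]


def _infer_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(path)[1].lower()
    return "," if ext == ".csv" else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dups.append(i)
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """A dense feature-by-sample matrix of non-negative expression values.

    Parameters
    ----------
    feature_ids : list of str
        Unique row identifiers (genes, transcripts, proteins ...).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray, shape (n_features, n_samples)
        Finite expression values. Non-negativity is enforced at construction
        but derived matrices (log2-transformed, z-scored, centered) legally
        carry negative values; they set ``require_non_negative=False``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    require_non_negative: bool = True

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/inf)")
        if self.require_non_negative and np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given features, in the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in index]
        if missing:
            raise KeyError(f"unknown feature ids: {', '.join(missing)}")
        rows = [index[f] for f in ids]
        return ExpressionMatrix(
            list(ids), list(self.sample_ids), self.values[rows, :],
            require_non_negative=False,
        )

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {', '.join(missing)}")
        cols = [index[s] for s in ids]
        return ExpressionMatrix(
            list(self.feature_ids), list(ids), self.values[:, cols],
            require_non_negative=False,
        )


@dataclass
class ComparisonDesign:
    """Binary class assignment for one comparison (e.g. LumA vs Basal).

    ``class_a`` is the first-named class and doubles as the positive class in
    downstream precision/recall reporting.
    """

    class_of: dict[str, str]
    class_a: str
    class_b: str

    def __post_init__(self) -> None:
        if self.class_a == self.class_b:
            raise ValueError("class_a and class_b must differ")
        labels = set(self.class_of.values())
        extra = labels - {self.class_a, self.class_b}
        if extra:
            raise ValueError(f"samples carry labels outside the comparison: {sorted(extra)}")
        for cls in (self.class_a, self.class_b):
            if sum(1 for v in self.class_of.values() if v == cls) < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.class_of)

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """0/1 vector: 0 for class_a, 1 for class_b."""
        missing = [s for s in sample_ids if s not in self.class_of]
        if missing:
            raise KeyError(f"samples without class label: {', '.join(missing)}")
        return np.array([0 if self.class_of[s] == self.class_a else 1 for s in sample_ids])

    def restrict(self, m: ExpressionMatrix) -> tuple[ExpressionMatrix, np.ndarray]:
        """Subset the matrix to labelled samples; return it with the 0/1 label vector."""
        keep = [s for s in m.sample_ids if s in self.class_of]
        sub = m.subset_samples(keep)
        return sub, self.labels_for(keep)


VariableKind = Literal["categorical", "ordinal", "ratio"]


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates; missing values (None/NaN) are allowed."""

    sample_ids: list[str]
    variables: dict[str, tuple[VariableKind, list]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        for name, (kind, vals) in self.variables.items():
            if kind not in ("categorical", "ordinal", "ratio"):
                raise ValueError(f"variable {name!r}: unknown kind {kind!r}")
            if len(vals) != len(self.sample_ids):
                raise ValueError(f"variable {name!r}: values not aligned to sample_ids")


def read_matrix(
    path: str,
    orientation: Literal["features_in_rows", "samples_in_rows"] = "features_in_rows",
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    The file has one header row and one leading identifier column; the body is
    numeric. ``orientation`` states what the file's rows are; the returned
    matrix is always features x samples.
    """
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    body = df.to_numpy()
    values = np.empty(body.shape, dtype=float)
    for i in range(body.shape[0]):
        for j in range(body.shape[1]):
            cell = body[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() in ("", "NA", "NaN", "nan"):
                raise ValueError(f"missing value at row {row_ids[i]!r}, column {col_ids[j]!r}")
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at row {row_ids[i]!r}, column {col_ids[j]!r}"
                ) from None
    if np.any(values < 0):
        i, j = map(int, np.argwhere(values < 0)[0])
        raise ValueError(f"negative value at row {row_ids[i]!r}, column {col_ids[j]!r}")
    if orientation == "samples_in_rows":
        row_ids, col_ids = col_ids, row_ids
        values = values.T
    elif orientation != "features_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(row_ids, col_ids, values)


def write_matrix(m: ExpressionMatrix, path: str, delimiter: str | None = None) -> None:
    """Write features x samples with 12 significant digits (round-trip safe)."""
    sep = _infer_delimiter(path, delimiter)
    m.to_frame().to_csv(path, sep=sep, float_format="%.12g")


def read_labels(path: str, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column sample -> class label file (header optional, ignored if named).

    Repeated samples with the same label are deduplicated; conflicting labels
    are an error.
    """
    sep = _infer_delimiter(path, delimiter)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            sample, label = parts[0].strip(), parts[1].strip()
            if lineno == 1 and label.lower() in ("label", "class", "group"):
                continue  # header row
            if sample in out and out[sample] != label:
                raise ValueError(
                    f"sample {sample!r} listed with conflicting labels "
                    f"{out[sample]!r} and {label!r}"
                )
            out[sample] = label
    return out


def read_clinical(path: str, kinds: Mapping[str, VariableKind] | None = None,
                  delimiter: str | None = None) -> ClinicalTable:
    """Read a clinical covariate table (rows = samples, columns = variables).

    ``kinds`` maps variable name -> kind; unlisted variables default to
    categorical if non-numeric, ratio otherwise. Empty cells and "NA" become
    missing values.
    """
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    variables: dict[str, tuple[VariableKind, list]] = {}
    for col in df.columns:
        raw = [None if (pd.isna(v) or str(v).strip() in ("", "NA")) else str(v).strip()
               for v in df[col]]
        kind = kinds.get(col) if kinds else None
        if kind is None:
            try:
                [float(v) for v in raw if v is not None]
                kind = "ratio"
            except ValueError:
                kind = "categorical"
        if kind in ("ordinal", "ratio"):
            vals = [None if v is None else float(v) for v in raw]
        else:
            vals = raw
        variables[col] = (kind, vals)
    return ClinicalTable(sample_ids, variables)


def write_ranking(ranking, path: str, fmt: Literal["csv", "tsv"] | None = None) -> None:
    """Export an ensemble ranking: one row per feature, sorted by rank.

    Columns: feature_id, ensemble_score, rank, then one column per
    contributing method's fold-averaged normalized score.
    """
    if not ranking.ensemble_score:
        raise ValueError("refusing to write an empty ranking")
    if fmt is None:
        fmt = "csv" if path.lower().endswith(".csv") else "tsv"
    sep = "," if fmt == "csv" else "\t"
    order = sorted(ranking.rank, key=ranking.rank.get)
    methods = list(ranking.method_table.method_scores)
    rows = []
    for f in order:
        row = {"feature_id": f,
               "ensemble_score": ranking.ensemble_score[f],
               "rank": ranking.rank[f]}
        for meth in methods:
            row[meth] = ranking.method_table.method_scores[meth][f]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.12g")
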