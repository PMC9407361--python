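"""Clinicopathological association tests.

Categorical variables vs. group membership are tested with the uncorrected
Pearson chi-square on the r x c contingency table (with a flag raised when
any expected count falls below 5, the usual validity caveat); ordinal and
ratio variables with the Kruskal-Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix_io import ClinicalTable

__all__ = ["ContingencyTable", "ChiSquareResult", "chi_square_test",
           "kruskal_wallis", "association_tests"]


@dataclass
class ContingencyTable:
    name: str
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError("contingency table needs >= 2 rows and >= 2 columns")
        if (len(self.row_labels), len(self.col_labels)) != (r, c):
            raise ValueError("labels do not match table shape")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ValueError("counts must be non-negative with a positive total")


@dataclass
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float
    low_expected_flag: bool


def chi_square_test(t: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square without continuity correction.

    ``low_expected_flag`` is True when any expected count under independence
    is below 5 (the test's small-sample caveat).
    """
    counts = np.asarray(t.counts, dtype=float)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError(f"{t.name}: zero row or column margin")
    res = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        dof=int(res.dof),
        p_value=float(res.pvalue),
        low_expected_flag=bool(res.expected_freq.min() < 5),
    )


def kruskal_wallis(groups: list[list[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with average-rank ties and tie correction.

    Returns (H, dof, p). All-identical values are the degenerate no-signal
    case: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    dof = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, dof, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), dof, float(p)


def association_tests(clinical: ClinicalTable, group_of: dict[str, str]) -> list[dict]:
    """Test every clinical variable against a sample grouping.

    Categorical variables go through ``chi_square_test`` on the
    variable x group crosstab; ordinal/ratio variables through
    ``kruskal_wallis`` across groups. Samples with a missing value (or no
    group) are dropped per variable, so each row reports its own n.
    """
    results = []
    groups_sorted = sorted(set(group_of.values()))
    for name, (kind, values) in clinical.variables.items():
        pairs = [
            (v, group_of[s])
            for s, v in zip(clinical.sample_ids, values)
            if v is not None and s in group_of
        ]
        if not pairs:
            continue
        if kind == "categorical":
            levels = sorted({v for v, _ in pairs})
            if len(levels) < 2:
                continue
            counts = np.zeros((len(levels), len(groups_sorted)), dtype=int)
            for v, g in pairs:
                counts[levels.index(v), groups_sorted.index(g)] += 1
            keep_cols = counts.sum(axis=0) > 0
            table = ContingencyTable(
                name, levels, [g for g, k in zip(groups_sorted, keep_cols) if k],
                counts[:, keep_cols],
            )
            res = chi_square_test(table)
            results.append({
                "variable": name, "test": "chi_square", "n": len(pairs),
                "statistic": res.statistic, "dof": res.dof, "p": res.p_value,
                "low_expected": res.low_expected_flag,
            })
        else:
            by_group = {g: [] for g in groups_sorted}
            for v, g in pairs:
                by_group[g].append(v)
            groups = [vals for vals in by_group.values() if vals]
            if len(groups) < 2:
                continue
            h, dof, p = kruskal_wallis(groups)
            results.append({
                "variable": name, "test": "kruskal_wallis", "n": len(pairs),
                "statistic": h, "dof": dof, "p": p, "low_expected": False,
            })
    return results
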