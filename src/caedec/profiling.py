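"""Cluster profiling: contingency analysis and validity indices.

Once records carry a cluster label, each covariate is cross-tabulated
against cluster membership, tested for association with Pearson's
chi-square, and decomposed cell-by-cell with Haberman adjusted
standardized residuals (approximately N(0,1) under independence, so
|residual| > 2 flags a cell driving the association).  Per-cluster
prevalence of a binary outcome and the intrinsic validity indices
(silhouette, Calinski-Harabasz, Davies-Bouldin) complete the profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "crosstab",
    "chi_square_test",
    "adjusted_residuals",
    "prevalence_by_cluster",
    "validity_indices",
    "format_p",
]


@dataclass
class ContingencyTable:
    """Observed category x cluster counts with margins."""

    observed: np.ndarray  # (r, c) integer counts
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        o = np.asarray(self.observed)
        if o.ndim != 2:
            raise ValueError("observed must be a 2-D count matrix")
        if np.any(o < 0) or not np.allclose(o, np.round(o)):
            raise ValueError("counts must be non-negative integers")
        self.observed = o.astype(np.int64)

    @property
    def row_margins(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.observed.sum())

    def expected(self) -> np.ndarray:
        return np.outer(self.row_margins, self.col_margins) / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.observed, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def crosstab(
    labels: Sequence, variable: Sequence, levels: Sequence[str] | None = None
) -> ContingencyTable:
    """Cross-tabulate a categorical variable (rows) against cluster
    labels (columns).  Declared-but-unobserved levels keep a zero row."""
    labels = np.asarray(labels)
    variable = np.asarray(variable, dtype=object)
    if len(labels) != len(variable):
        raise ValueError(f"length mismatch: {len(labels)} labels vs {len(variable)} values")
    row_levels = [str(v) for v in levels] if levels is not None else sorted(
        {str(v) for v in variable}
    )
    col_levels = sorted({int(l) for l in labels})
    o = np.zeros((len(row_levels), len(col_levels)), dtype=np.int64)
    ri = {lvl: i for i, lvl in enumerate(row_levels)}
    ci = {lvl: j for j, lvl in enumerate(col_levels)}
    for lab, val in zip(labels, variable):
        key = str(val)
        if key not in ri:
            raise ValueError(f"value {val!r} not among declared levels {row_levels}")
        o[ri[key], ci[int(lab)]] += 1
    return ContingencyTable(o, tuple(row_levels), tuple(str(c) for c in col_levels))


def _nondegenerate(t: ContingencyTable) -> ContingencyTable:
    """Drop all-zero rows/columns (warning cases) and demand a proper table."""
    o = t.observed
    keep_r = o.sum(axis=1) > 0
    keep_c = o.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        import warnings

        warnings.warn("dropping all-zero rows/columns before the chi-square test",
                      stacklevel=3)
        o = o[keep_r][:, keep_c]
        t = ContingencyTable(
            o,
            tuple(l for l, k in zip(t.row_labels, keep_r) if k),
            tuple(l for l, k in zip(t.col_labels, keep_c) if k),
        )
    if t.n == 0 or min(t.observed.shape) < 2:
        raise ValueError("chi-square needs at least a 2x2 table with observations")
    return t


def chi_square_test(t: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, df = (r-1)(c-1)."""
    t = _nondegenerate(t)
    stat, p, df, _ = stats.chi2_contingency(t.observed, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


def adjusted_residuals(t: ContingencyTable) -> np.ndarray:
    """Haberman adjusted standardized residuals.

    cell (i, j):  (O - E) / sqrt(E * (1 - row_i/n) * (1 - col_j/n)).
    Cells with zero expected count are returned as NaN.
    """
    t = _nondegenerate(t)
    o = t.observed.astype(float)
    e = t.expected()
    n = t.n
    adj = np.outer(1.0 - t.row_margins / n, 1.0 - t.col_margins / n)
    denom = np.sqrt(e * adj)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (o - e) / denom, np.nan)
    return r


def prevalence_by_cluster(
    labels: Sequence[int], outcome: Sequence[int]
) -> pd.DataFrame:
    """Per-cluster count and percentage of positive binary outcomes.

    Percentages are 100 * positives / cluster size, reported to two
    decimals; an empty cluster gets a NaN percentage.
    """
    labels = np.asarray(labels)
    outcome = np.asarray(outcome)
    if len(labels) != len(outcome):
        raise ValueError("labels and outcome must align")
    if not set(np.unique(outcome)) <= {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    rows = []
    for m in sorted(np.unique(labels)):
        mask = labels == m
        size = int(mask.sum())
        pos = int(outcome[mask].sum())
        pct = round(100.0 * pos / size, 2) if size else np.nan
        rows.append({"cluster": int(m), "n": size, "positives": pos, "percent": pct})
    return pd.DataFrame(rows)


def validity_indices(
    x: np.ndarray, labels: Sequence[int]
) -> tuple[float, float, float]:
    """(silhouette, Calinski-Harabasz, Davies-Bouldin) of a labelling."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("validity indices need at least two clusters")
    if np.any(counts == 0):
        raise ValueError("every cluster must be non-empty")
    x = np.asarray(x, dtype=float)
    return (
        float(silhouette_score(x, labels)),
        float(calinski_harabasz_score(x, labels)),
        float(davies_bouldin_score(x, labels)),
    )


def format_p(p: float) -> str:
    """Display convention: probabilities below 1e-4 print as '< .0001'."""
    return "< .0001" if p < 1e-4 else f"{p:.4f}"
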