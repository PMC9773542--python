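"""Two-group comparison policy for per-organoid metrics.

Policy: a two-tailed Mann-Whitney U test when either group is small
(fewer than ``small_n_cutoff`` samples; exact null distribution when there
are no ties, normal approximation otherwise), Welch's unequal-variance t
test otherwise. Student's t is available by explicit request (used for
calcium-kinetics and qPCR-style comparisons). The test actually applied is
recorded in every result, and significance is annotated with the usual
star convention (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).

No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_two_groups", "stars", "compare_table"]

_STAR_THRESHOLDS: Tuple[Tuple[float, str], ...] = (
    (0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"),
)


@dataclass(frozen=True)
class GroupComparison:
    """One two-group test result with its provenance."""

    metric: str
    group_labels: Tuple[str, str]
    n: Tuple[int, int]
    test: str           # student_t | welch_t | mann_whitney
    statistic: float
    p_value: float
    stars: str

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "group_a": self.group_labels[0], "group_b": self.group_labels[1],
            "n_a": self.n[0], "n_b": self.n[1],
            "test": self.test, "statistic": self.statistic,
            "p_value": self.p_value, "stars": self.stars,
        }


def stars(p: float) -> str:
    """Significance label for a p-value (ns, *, **, ***, ****)."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    for threshold, label in _STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


def compare_two_groups(
    x: Sequence[float],
    y: Sequence[float],
    *,
    metric: str = "",
    labels: Tuple[str, str] = ("a", "b"),
    small_n_cutoff: int = 8,
    test: Optional[str] = None,
) -> GroupComparison:
    """Compare two samples under the small-n policy (two-sided throughout).

    ``test`` forces ``"student_t"``, ``"welch_t"`` or ``"mann_whitney"``;
    by default the choice follows ``min(n) < small_n_cutoff``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if test is None:
        test = "mann_whitney" if min(x.size, y.size) < small_n_cutoff else "welch_t"
    if test == "mann_whitney":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    elif test == "welch_t":
        res = sps.ttest_ind(x, y, equal_var=False)
    elif test == "student_t":
        res = sps.ttest_ind(x, y, equal_var=True)
    else:
        raise ValueError(f"unknown test: {test!r}")
    p = float(res.pvalue)
    return GroupComparison(
        metric=metric, group_labels=labels, n=(int(x.size), int(y.size)),
        test=test, statistic=float(res.statistic), p_value=p, stars=stars(p),
    )


def compare_table(
    metrics: pd.DataFrame,
    *,
    group_col: str = "group",
    metric_cols: Optional[Sequence[str]] = None,
    reference: Optional[str] = None,
    small_n_cutoff: int = 8,
    test: Optional[str] = None,
) -> pd.DataFrame:
    """All pairwise (or reference-vs-other) comparisons per metric column.

    Returns one row per (metric, group pair) in long format, ready to write
    as the cohort comparison CSV.
    """
    if group_col not in metrics.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = list(pd.unique(metrics[group_col]))
    if metric_cols is None:
        metric_cols = [c for c in metrics.columns
                       if c != group_col and pd.api.types.is_numeric_dtype(metrics[c])]
    if reference is not None:
        pairs = [(reference, g) for g in groups if g != reference]
    else:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    rows = []
    for m in metric_cols:
        for a, b in pairs:
            xa = metrics.loc[metrics[group_col] == a, m].dropna()
            xb = metrics.loc[metrics[group_col] == b, m].dropna()
            cmp_ = compare_two_groups(xa, xb, metric=m, labels=(str(a), str(b)),
                                      small_n_cutoff=small_n_cutoff, test=test)
            rows.append(cmp_.to_dict())
    return pd.DataFrame(rows)
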