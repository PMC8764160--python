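"""Two-group comparison layer.

Microstate temporal parameters are compared between two subject groups with
the two-sided Wilcoxon rank-sum (Mann-Whitney) test; the 12 syntax doublets
are tested jointly under Benjamini-Hochberg FDR control (q < 0.01 default);
demographics use Welch's two-tailed t-test; discrimination is summarized by
the empirical ROC and its area (which equals the Mann-Whitney U statistic
scaled by 1/(n1*n2), ties counted one half); an ordinal clinical score is
related to the metrics by Spearman rank correlation.

The rank-sum test is exact for small groups (n <= 10 per group): the null
distribution is enumerated directly over all splits of the pooled mid-ranks,
which handles ties exactly.  Larger groups use the tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .metrics import syntax_pairs

__all__ = [
    "TestResult",
    "RocResult",
    "rank_sum_test",
    "fdr_adjust",
    "syntax_comparison",
    "two_sample_t_test",
    "roc_auc",
    "clinical_correlation",
    "compare_metric_table",
]

EXACT_MAX_N = 10  # per group; above this the normal approximation is used


@dataclass
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float

    def fmt(self, digits: int = 3) -> str:
        return (f"{self.median:.{digits}f} "
                f"({self.q1:.{digits}f}, {self.q3:.{digits}f})")


@dataclass
class TestResult:
    metric_name: str
    statistic: float
    p_value: float
    method: str
    q_value: Optional[float] = None
    significant: Optional[bool] = None
    group_summaries: Optional[tuple[GroupSummary, GroupSummary]] = None
    auc: Optional[float] = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if self.q_value is not None and not np.isnan(self.q_value):
            if self.q_value < self.p_value - 1e-12:
                raise ValueError("q_value cannot be below p_value")


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    positive_group: int  # 1 or 2: which input group plays "positive"
    direction: str  # "greater" if positives tend to larger values


def _summary(values: np.ndarray) -> GroupSummary:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return GroupSummary(n=values.size, median=float(med),
                        q1=float(q1), q3=float(q3))


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, w1: float) -> float:
    """Two-sided exact p by enumerating all C(n, n1) rank splits."""
    n = ranks.size
    idx = np.fromiter(
        (i for c in combinations(range(n), n1) for i in c), dtype=int,
        count=comb(n, n1) * n1,
    ).reshape(-1, n1)
    sums = ranks[idx].sum(axis=1)
    eps = 1e-9
    p_le = np.mean(sums <= w1 + eps)
    p_ge = np.mean(sums >= w1 - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def rank_sum_test(
    values_group1: Sequence[float],
    values_group2: Sequence[float],
    metric_name: str = "metric",
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Reports the Mann-Whitney U of group 1 and median (Q1, Q3) summaries.
    Exact enumeration over mid-rank splits for n <= 10 per group; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)  # mid-ranks
    w1 = float(ranks[:n1].sum())
    u1 = w1 - n1 * (n1 + 1) / 2.0

    if max(n1, n2) <= EXACT_MAX_N:
        p = _exact_rank_sum_p(ranks, n1, w1)
        method = "exact"
    else:
        _, p = sstats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
        p = float(p)
        method = "normal-approximation"
    return TestResult(
        metric_name=metric_name,
        statistic=u1,
        p_value=p,
        method=f"wilcoxon-rank-sum ({method})",
        group_summaries=(_summary(x), _summary(y)),
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def syntax_comparison(
    metrics_frame: pd.DataFrame,
    groups: Sequence[str],
    class_labels: Sequence[str] = ("A", "B", "C", "D"),
    fdr_q: float = 0.01,
) -> list[TestResult]:
    """Rank-sum test per syntax doublet with BH-FDR across the 12 of them.

    ``metrics_frame`` needs one ``syntax_XY`` column per ordered doublet;
    ``groups`` assigns each row to one of exactly two group labels.
    """
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    pairs = syntax_pairs(class_labels)
    missing = [p for p in pairs if f"syntax_{p}" not in metrics_frame.columns]
    if missing:
        raise ValueError(f"metrics table lacks syntax columns: {missing}")
    bad = metrics_frame[[f"syntax_{p}" for p in pairs]].isna().any(axis=1)
    if bad.any():
        who = metrics_frame.loc[bad, "subject_id"].tolist() \
            if "subject_id" in metrics_frame else list(np.flatnonzero(bad))
        raise ValueError(f"missing syntax values for subjects: {who}")

    results = []
    for p in pairs:
        col = metrics_frame[f"syntax_{p}"].to_numpy()
        res = rank_sum_test(col[groups == uniq[0]], col[groups == uniq[1]],
                            metric_name=f"syntax_{p}")
        results.append(res)
    q = fdr_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.significant = bool(qv < fdr_q)
    return results


def two_sample_t_test(
    values_group1: Sequence[float],
    values_group2: Sequence[float],
    metric_name: str = "metric",
) -> TestResult:
    """Welch's two-tailed t-test (unequal variances)."""
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        # degenerate: convention p=1 when the constant groups coincide
        equal = np.isclose(x.mean(), y.mean())
        return TestResult(metric_name, 0.0 if equal else np.inf,
                          1.0 if equal else 0.0, "welch-t (degenerate)",
                          group_summaries=(_summary(x), _summary(y)))
    t, p = sstats.ttest_ind(x, y, equal_var=False)
    return TestResult(metric_name, float(t), float(p), "welch-t",
                      group_summaries=(_summary(x), _summary(y)))


def roc_auc(
    values_group1: Sequence[float],
    values_group2: Sequence[float],
) -> RocResult:
    """Empirical ROC for discriminating the two groups by one metric.

    AUC is the Mann-Whitney U scaled by 1/(n1*n2) with ties counted one
    half.  Orientation is chosen so AUC >= 0.5 and reported explicitly:
    ``positive_group`` says which group plays the positive class and
    ``direction`` whether its values tend to be greater or smaller.
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least 1 value")
    n1, n2 = x.size, y.size
    ranks = sstats.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc1 = u1 / (n1 * n2)  # P(X > Y) + 0.5 P(X = Y)
    if auc1 >= 0.5:
        pos, scores_pos, scores_neg, direction = 1, x, y, "greater"
        auc = float(auc1)
    else:
        pos, scores_pos, scores_neg, direction = 2, y, x, "greater"
        auc = float(1.0 - auc1)

    thresholds = np.unique(np.concatenate([scores_pos, scores_neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(scores_pos >= t)))
        fpr.append(float(np.mean(scores_neg >= t)))
    return RocResult(auc=auc, fpr=np.asarray(fpr), tpr=np.asarray(tpr),
                     positive_group=pos, direction=direction)


def clinical_correlation(
    metric_values: Sequence[float],
    clinical_scores: Sequence[float],
    metric_name: str = "metric",
) -> TestResult:
    """Spearman rank correlation between a metric and an ordinal score."""
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(clinical_scores, dtype=float)
    if x.size != y.size:
        raise ValueError("metric and clinical scores must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return TestResult(metric_name, float("nan"), float("nan"),
                          "spearman (undefined: constant input)")
    rho, p = sstats.spearmanr(x, y)
    return TestResult(metric_name, float(rho), float(p), "spearman")


def compare_metric_table(
    metrics_frame: pd.DataFrame,
    groups: Sequence[str],
    columns: Optional[Sequence[str]] = None,
    roc_columns: Sequence[str] = ("duration_mean", "occurrence_mean"),
) -> tuple[pd.DataFrame, dict]:
    """Rank-sum comparison of every metric column between two groups.

    Returns a tidy results table (metric, per-group median (Q1, Q3), U, p,
    and AUC for the requested columns) plus the RocResult objects keyed by
    column, for curve export.
    """
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 groups, got {list(uniq)}")
    if columns is None:
        columns = [
            c for c in metrics_frame.columns
            if c.startswith(("duration_", "occurrence_", "coverage_"))
        ]
    rows = []
    rocs: dict = {}
    for col in columns:
        v = metrics_frame[col].to_numpy()
        g1, g2 = v[groups == uniq[0]], v[groups == uniq[1]]
        ok1, ok2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
        res = rank_sum_test(ok1, ok2, metric_name=col)
        row = {
            "metric": col,
            f"{uniq[0]}_median_q1_q3": res.group_summaries[0].fmt(),
            f"{uniq[1]}_median_q1_q3": res.group_summaries[1].fmt(),
            "U": res.statistic,
            "p": res.p_value,
        }
        if col in roc_columns:
            roc = roc_auc(ok1, ok2)
            rocs[col] = roc
            row["auc"] = roc.auc
        rows.append(row)
    return pd.DataFrame(rows), rocs
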