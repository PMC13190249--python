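"""Normality-gated two-group comparisons and tabular summaries.

Policy: both groups are screened with the D'Agostino-Pearson omnibus
test (alpha 0.05).  If both pass, an unpaired two-sided t-test is used
(Welch's variant when the variance ratio exceeds 4); otherwise the
two-sided Mann-Whitney U test.  Groups smaller than 8 cannot be screened
and fall straight to Mann-Whitney.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupComparison", "SummaryRecord", "compare_groups", "summarize"]

NORMALITY_ALPHA = 0.05
MIN_N_GATE = 8
WELCH_VAR_RATIO = 4.0


@dataclass
class GroupComparison:
    metric: str
    n_a: int
    n_b: int
    test_used: str  # "t" | "welch" | "mann_whitney"
    statistic: float
    p: float
    gate_note: str = ""


@dataclass
class SummaryRecord:
    style: str  # "mean_sem" | "mean_sd" | "median_iqr"
    center: float
    spread: float
    n: int

    def __str__(self) -> str:
        if self.style == "median_iqr":
            return f"{self.center:g} ({self.spread:g})"
        return f"{self.center:g} ± {self.spread:g}"


def compare_groups(a: np.ndarray, b: np.ndarray, metric: str = "",
                   alpha_normal: float = NORMALITY_ALPHA) -> GroupComparison:
    """Two-group comparison with the normality-gated test choice."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    note = ""
    constant = np.all(a == a[0]) or np.all(b == b[0])
    if constant:
        note = "constant-valued group; Mann-Whitney with tie correction"
        warnings.warn(note, stacklevel=2)
        test = "mann_whitney"
    elif min(a.size, b.size) < MIN_N_GATE:
        note = f"n < {MIN_N_GATE}: normality gate skipped"
        test = "mann_whitney"
    else:
        pa = stats.normaltest(a).pvalue
        pb = stats.normaltest(b).pvalue
        if pa > alpha_normal and pb > alpha_normal:
            var_ratio = max(a.var(ddof=1), b.var(ddof=1)) / max(
                min(a.var(ddof=1), b.var(ddof=1)), 1e-300)
            test = "welch" if var_ratio > WELCH_VAR_RATIO else "t"
        else:
            test = "mann_whitney"

    if test == "mann_whitney":
        if np.array_equal(a, b) and constant:
            stat, p = float(a.size * b.size / 2), 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.ttest_ind(a, b, equal_var=(test == "t"))
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(metric=metric, n_a=a.size, n_b=b.size,
                           test_used=test, statistic=stat, p=p, gate_note=note)


def summarize(values: np.ndarray, style: str = "mean_sem") -> SummaryRecord:
    """Mean +/- SEM, mean +/- SD, or median (IQR) summary."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty sample")
    if style == "mean_sem":
        spread = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        return SummaryRecord(style, float(v.mean()), spread, v.size)
    if style == "mean_sd":
        spread = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return SummaryRecord(style, float(v.mean()), spread, v.size)
    if style == "median_iqr":
        q1, q3 = np.percentile(v, [25, 75])
        return SummaryRecord(style, float(np.median(v)), float(q3 - q1), v.size)
    raise ValueError(f"unknown summary style {style!r}")
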