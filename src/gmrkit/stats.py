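"""First-principles implementations of the study's statistical procedures.

Every statistic here (one-way ANOVA F, paired t, Spearman's rho, the
Shrout-Fleiss intraclass correlations) is computed from its closed-form
mean-squares / rank formula; scipy is used only for the reference
distributions' tail probabilities.  Two-sided p-values throughout, no
multiple-testing correction, significance conventionally at 5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .types import AGE_GROUPS


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test."""

    name: str  # "F", "t", "rho", "ICC11", "ICC21"
    value: float
    df: tuple  # (df1, df2) for F; (df,) otherwise; () for ICC
    p_value: Optional[float] = None
    degenerate: bool = False


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / sd of one numeric column within one group."""

    group: str
    n: int
    mean: float
    sd: Optional[float]  # absent when n == 1

    @classmethod
    def from_values(cls, group: str, values: Sequence[float]) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if len(v) < 1:
            raise ValueError("group summary requires n >= 1")
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else None
        return cls(group=group, n=len(v), mean=float(np.mean(v)), sd=sd)


def classify_smoking_status(
    lifetime_cigarettes: float, smoked_last_30_days: bool
) -> str:
    """Current / former / ineligible per the >100-lifetime-cigarettes rule.

    Current smokers exceed 100 lifetime cigarettes and smoked within the
    previous 30 days; former smokers exceed 100 but did not.  Anyone at or
    below 100 lifetime cigarettes fits neither definition.
    """
    if lifetime_cigarettes > 100:
        return "current" if smoked_last_30_days else "former"
    return "ineligible"


def assign_age_group(age: float) -> str:
    """Ten-year age bin label; the study range starts at 19 and is open above 60."""
    if age < 19:
        raise ValueError(f"age {age} below the study range (19+)")
    if age <= 29:
        return AGE_GROUPS[0]
    if age <= 39:
        return AGE_GROUPS[1]
    if age <= 49:
        return AGE_GROUPS[2]
    if age <= 59:
        return AGE_GROUPS[3]
    return AGE_GROUPS[4]


def pooled_mean(groups: Sequence[tuple[float, int]]) -> float:
    """Size-weighted mean of group means: sum(mean_i * n_i) / sum(n_i)."""
    if not groups:
        raise ValueError("pooled_mean of an empty group list")
    if any(n < 1 for _, n in groups):
        raise ValueError("all group sizes must be >= 1")
    total_n = sum(n for _, n in groups)
    return sum(m * n for m, n in groups) / total_n


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Fixed-effects one-way ANOVA: F = MS_between / MS_within."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if any(len(g) < 1 for g in gs):
        raise ValueError("every group must be non-empty")
    n_total = sum(len(g) for g in gs)
    k = len(gs)
    if n_total <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.mean(np.concatenate(gs))
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in gs)
    ss_within = sum(np.sum((g - np.mean(g)) ** 2) for g in gs)
    df1, df2 = k - 1, n_total - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        if ms_between == 0:
            return TestResult("F", 0.0, (df1, df2), p_value=1.0)
        return TestResult("F", float("inf"), (df1, df2), p_value=0.0, degenerate=True)
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df1, df2))
    return TestResult("F", float(f), (df1, df2), p_value=p)


def paired_t(baseline: Sequence[float], followup: Sequence[float]) -> TestResult:
    """Paired t-test on d = followup - baseline; t = mean(d) / (sd(d)/sqrt(n))."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("baseline and followup must be equal-length vectors")
    n = len(b)
    if n < 2:
        raise ValueError("paired t-test requires n >= 2 pairs")
    d = f - b
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    df = n - 1
    if sd_d == 0:
        if mean_d == 0:
            return TestResult("t", 0.0, (df,), p_value=1.0)
        t = float(np.sign(mean_d)) * float("inf")
        return TestResult("t", t, (df,), p_value=0.0, degenerate=True)
    t = mean_d / (sd_d / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult("t", float(t), (df,), p_value=p)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the rank vectors; the p-value uses the
    t approximation t = rho * sqrt((n-2)/(1-rho^2)) with n-2 df.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or len(xa) < 3:
        raise ValueError("spearman_rho requires equal-length vectors, n >= 3")
    rx, ry = _midranks(xa), _midranks(ya)
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0 or sy == 0:
        raise ValueError("rank variance is zero; rho undefined")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    n = len(xa)
    if abs(rho) == 1.0:
        return TestResult("rho", rho, (n - 2,), p_value=0.0)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return TestResult("rho", rho, (n - 2,), p_value=p)


def spearman_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided permutation p-value for Spearman's rho (n <= 10).

    Enumerates all n! permutations of y; intended as a small-sample oracle
    for the t approximation, not for routine use.
    """
    from itertools import permutations

    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(xa)
    if n > 10:
        raise ValueError("exact permutation p restricted to n <= 10")
    rx, ry = _midranks(xa), _midranks(ya)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(ry):
        r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def icc(ratings: np.ndarray, model: str = "one_way") -> TestResult:
    """Single-rater intraclass correlation from ANOVA mean squares.

    ``ratings`` is an n-targets x k-raters matrix with no missing cells.
    ``model="one_way"`` gives ICC(1,1) (repeatability of one examiner over
    sessions); ``model="two_way"`` gives ICC(2,1) (stability between
    examiners, two-way random effects):

    - ICC(1,1) = (BMS - WMS) / (BMS + (k-1) WMS)
    - ICC(2,1) = (BMS - EMS) / (BMS + (k-1) EMS + k (JMS - EMS) / n)

    where BMS/WMS/JMS/EMS are the between-target, within-target, between-
    rater and residual mean squares.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ratings must be an n x k matrix with n, k >= 2")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must be complete")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = np.sum((m - grand) ** 2)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    bms = ss_rows / (n - 1)
    if model == "one_way":
        wms = (ss_total - ss_rows) / (n * (k - 1))
        if bms == 0 and wms == 0:
            raise ValueError("constant ratings matrix; ICC undefined")
        value = (bms - wms) / (bms + (k - 1) * wms)
        return TestResult("ICC11", float(value), ())
    if model == "two_way":
        jms = ss_cols / (k - 1)
        ems = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
        denom = bms + (k - 1) * ems + k * (jms - ems) / n
        if denom == 0:
            raise ValueError("degenerate ratings matrix; ICC undefined")
        value = (bms - ems) / denom
        return TestResult("ICC21", float(value), ())
    raise ValueError(f"unknown ICC model: {model!r}")
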