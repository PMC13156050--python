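"""Group comparison of demographic variables, from raw rows or printed
summary statistics.

Continuous variables are compared with a two-sample t-test: Welch's
unequal-variance form when the larger-to-smaller sample-variance ratio
reaches a configurable threshold (default 1.30), the pooled form otherwise.
Categorical variables use the Pearson chi-square without continuity
correction.  Because the t statistics depend only on (mean, SD, n) per
group, raw-data and summary-statistics modes give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TestResult",
    "DemographicsReport",
    "two_sample_t",
    "chi_square_counts",
    "demographics_from_summary",
    "demographics",
    "VARIANCE_RATIO_THRESHOLD",
]

#: variance-ratio gate above which Welch's t replaces the pooled t
VARIANCE_RATIO_THRESHOLD = 1.30


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TestResult:
    variable: str
    test: str  # 'pooled', 'welch' or 'chi2'
    statistic: float
    df: float
    p: float


@dataclass
class DemographicsReport:
    results: dict[str, TestResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "test": r.test,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p": r.p,
                }
                for r in self.results.values()
            ]
        )


def two_sample_t(
    a: GroupSummary,
    b: GroupSummary,
    variance_ratio_threshold: float = VARIANCE_RATIO_THRESHOLD,
    variable: str = "",
) -> TestResult:
    """t-test for group a vs b from summary statistics.

    The statistic is (mean_a - mean_b) / SE with the pooled or Welch SE
    chosen by the variance-ratio rule; df is n_a + n_b - 2 (pooled) or the
    Welch-Satterthwaite approximation.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.sd**2, b.sd**2
    ratio = max(va, vb) / min(va, vb) if min(va, vb) > 0 else np.inf
    if ratio >= variance_ratio_threshold:
        se = np.sqrt(va / a.n + vb / b.n)
        df = (va / a.n + vb / b.n) ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        )
        test = "welch"
    else:
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = a.n + b.n - 2
        test = "pooled"
    t = (a.mean - b.mean) / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), df) if se > 0 else 1.0
    return TestResult(variable, test, float(t), float(df), float(p))


def chi_square_counts(table, variable: str = "sex") -> TestResult:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    table = np.asarray(table, dtype=float)
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(variable, "chi2", float(res.statistic), float(res.dof), float(res.pvalue))


def demographics_from_summary(
    continuous: dict[str, tuple[GroupSummary, GroupSummary]],
    categorical: dict[str, np.ndarray] | None = None,
    variance_ratio_threshold: float = VARIANCE_RATIO_THRESHOLD,
) -> DemographicsReport:
    """Report from printed (mean, SD, n) summaries and contingency tables."""
    out: dict[str, TestResult] = {}
    for name, (a, b) in continuous.items():
        out[name] = two_sample_t(a, b, variance_ratio_threshold, variable=name)
    for name, table in (categorical or {}).items():
        out[name] = chi_square_counts(table, variable=name)
    return DemographicsReport(out)


def demographics(
    cohort: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("patient", "control"),
    continuous: tuple[str, ...] = ("age", "education", "tiv"),
    categorical: tuple[str, ...] = ("sex",),
    variance_ratio_threshold: float = VARIANCE_RATIO_THRESHOLD,
) -> DemographicsReport:
    """Report from raw cohort rows (identical to the summary-mode result)."""
    ga = cohort[cohort[group_col] == groups[0]]
    gb = cohort[cohort[group_col] == groups[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("both groups need at least 2 rows")
    cont = {}
    for var in continuous:
        cont[var] = (
            GroupSummary(ga[var].mean(), ga[var].std(ddof=1), len(ga)),
            GroupSummary(gb[var].mean(), gb[var].std(ddof=1), len(gb)),
        )
    cat = {}
    for var in categorical:
        levels = sorted(cohort[var].dropna().unique())
        cat[var] = np.array(
            [[int((g[var] == lv).sum()) for lv in levels] for g in (ga, gb)]
        )
    return demographics_from_summary(cont, cat, variance_ratio_threshold)
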