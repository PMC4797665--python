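"""Two-group moderator and outcome tests on usage-indicator variables.

After a usage pattern is spotted in the plots, a 0/1 usage variable is
created (who did / did not exhibit the pattern) and participant
characteristics and outcomes are compared between the two groups:

* numeric variables — pooled two-sample t test by default,
  Welch's unequal-variance t on request;
* categorical variables — Pearson chi-square on the contingency table.

Both t tests accept either raw samples or published summaries
(n, mean, sample SD), so printed group summaries can be re-analyzed
without the raw data.  Sample SDs use the n−1 denominator throughout.
The group order convention is (indicator=0 group) − (indicator=1 group);
a negative t therefore means the users of a component scored higher.
All p values are two-sided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataio import Dataset, UsageDataError


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample SD (n−1 denominator) of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ValueError("need at least 2 observations for a summary with SD")
        return cls(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    """Test statistic (t or chi-square), degrees of freedom (fractional for
    Welch), and two-sided p value."""

    statistic: float
    df: float
    p: float
    test: str = ""

    def __post_init__(self):
        if not (0 <= self.p <= 1):
            raise ValueError(f"p must be in [0, 1], got {self.p}")


def _check_ns(a: GroupSummary, b: GroupSummary):
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2 for a variance-based test")


def pooled_t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Pooled-variance two-sample t test from group summaries.

    t = (m_a − m_b) / (s_p · sqrt(1/n_a + 1/n_b)) with the pooled variance
    s_p² = ((n_a−1)s_a² + (n_b−1)s_b²) / (n_a+n_b−2) and df = n_a+n_b−2.
    Zero pooled variance with equal means yields t=0, p=1; with unequal
    means the t is infinite and a warning is issued.
    """
    _check_ns(a, b)
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    diff = a.mean - b.mean
    if se == 0:
        if diff == 0:
            return TestResult(0.0, df, 1.0, "pooled t")
        warnings.warn("zero pooled variance with unequal means: infinite t")
        return TestResult(math.copysign(math.inf, diff), df, 0.0, "pooled t")
    t = diff / se
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "pooled t")


def pooled_t_from_samples(x, y) -> TestResult:
    """Pooled t from raw samples; equals the summary route exactly."""
    return pooled_t_from_summary(GroupSummary.from_sample(x), GroupSummary.from_sample(y))


def welch_t(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Welch's unequal-variance t test from group summaries.

    t = (m_a − m_b) / sqrt(s_a²/n_a + s_b²/n_b); df by Welch–Satterthwaite,
    which is fractional in general and never exceeds n_a+n_b−2.
    """
    _check_ns(a, b)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    diff = a.mean - b.mean
    if se2 == 0:
        df = a.n + b.n - 2
        if diff == 0:
            return TestResult(0.0, df, 1.0, "welch t")
        warnings.warn("zero variance with unequal means: infinite t")
        return TestResult(math.copysign(math.inf, diff), df, 0.0, "welch t")
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = diff / math.sqrt(se2)
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "welch t")


def welch_t_from_samples(x, y) -> TestResult:
    return welch_t(GroupSummary.from_sample(x), GroupSummary.from_sample(y))


def chi_square(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r×c count table.

    Expected counts come from the margins; df = (r−1)(c−1).  No continuity
    correction by default.  A zero row/column margin is an error (an
    expected count of zero).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UsageDataError("zero margin in contingency table (expected count 0)")
    res = sps.chi2_contingency(table, correction=correction)
    return TestResult(float(res.statistic), float(res.dof), float(res.pvalue), "chi-square")


def benjamini_hochberg(pvalues) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvalues, method="fdr_bh")[1]


def moderator_report(
    dataset_or_users,
    indicator: str,
    variables: list[str],
    outcome: str | None = None,
    welch: bool = False,
    adjust: bool = False,
) -> pd.DataFrame:
    """Compare every variable (and optionally the outcome) between the two
    levels of a binary usage indicator.

    Numeric variables get a pooled t (Welch if ``welch=True``); categorical
    variables get a chi-square on the indicator×level contingency table.
    The t sign follows (indicator=0) − (indicator=1).  Rows:
    variable, test, statistic, df, p, n0, n1, mean0, sd0, mean1, sd1
    (means/SDs empty for chi-square), plus ``p_bh`` when ``adjust=True``.
    """
    users = dataset_or_users.users if isinstance(dataset_or_users, Dataset) else dataset_or_users
    if indicator not in users.columns:
        raise UsageDataError(f"unknown indicator {indicator!r}")
    ind = users[indicator]
    if not set(ind.dropna().unique()) <= {0, 1}:
        raise UsageDataError(f"indicator {indicator!r} must be binary 0/1")
    if ind.nunique() < 2:
        raise UsageDataError(f"indicator {indicator!r} is constant: one group is empty")
    names = list(variables) + ([outcome] if outcome and outcome not in variables else [])
    rows = []
    for var in names:
        if var not in users.columns:
            raise UsageDataError(f"unknown variable {var!r}")
        col = users[var]
        mask = col.notna() & ind.notna()
        g0, g1 = col[mask & (ind == 0)], col[mask & (ind == 1)]
        if pd.api.types.is_numeric_dtype(col):
            a = GroupSummary.from_sample(g0)
            b = GroupSummary.from_sample(g1)
            res = welch_t(a, b) if welch else pooled_t_from_summary(a, b)
            rows.append(
                (var, res.test, res.statistic, res.df, res.p,
                 a.n, b.n, a.mean, a.sd, b.mean, b.sd)
            )
        else:
            table = pd.crosstab(ind[mask], col[mask]).to_numpy()
            res = chi_square(table)
            rows.append(
                (var, res.test, res.statistic, res.df, res.p,
                 int(len(g0)), int(len(g1)), np.nan, np.nan, np.nan, np.nan)
            )
    report = pd.DataFrame(
        rows,
        columns=["variable", "test", "statistic", "df", "p",
                 "n0", "n1", "mean0", "sd0", "mean1", "sd1"],
    )
    if adjust and len(report):
        report["p_bh"] = benjamini_hochberg(report["p"].to_numpy())
    return report


def analytic_two_sample_power(
    n0: int, n1: int, delta: float, sd: float, alpha: float = 0.05
) -> float:
    """Power of the pooled two-sample t test for a true mean difference
    ``delta`` with common SD ``sd``, via the noncentral t distribution."""
    df = n0 + n1 - 2
    ncp = delta / (sd * math.sqrt(1 / n0 + 1 / n1))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
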