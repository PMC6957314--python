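"""Statistical battery used across the pipeline.

Thin, auditable wrappers over scipy.stats: two-tailed paired and Welch
t tests, one-way ANOVA with Bonferroni-adjusted pairwise post hoc t tests,
and OLS linear regression.  Test selection is never automatic — pipeline
configs name the test per comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

SIGNIFICANCE_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_tier(p: float) -> str:
    for cut, mark in SIGNIFICANCE_TIERS:
        if p < cut:
            return mark
    return "ns"


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: tuple  # one- or two-element
    p_two_sided: float
    effect: float  # mean difference, F, or slope
    extra: Optional[dict] = None

    @property
    def tier(self) -> str:
        return significance_tier(self.p_two_sided)


def paired_t(x, y) -> TestResult:
    """Two-tailed paired t test on matched samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 matched pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = sps.ttest_rel(x, y)
    return TestResult(
        method="paired_t",
        statistic=float(res.statistic),
        df=(x.size - 1,),
        p_two_sided=float(res.pvalue),
        effect=float(d.mean()),
    )


def welch_t(x, y) -> TestResult:
    """Two-tailed Welch t test (Satterthwaite df) on independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValueError("both groups degenerate: Welch t undefined")
    res = sps.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    return TestResult(
        method="welch_t",
        statistic=float(res.statistic),
        df=(float(df),),
        p_two_sided=float(res.pvalue),
        effect=float(x.mean() - y.mean()),
    )


def anova_bonferroni(groups) -> TestResult:
    """One-way ANOVA plus Bonferroni-adjusted pairwise Student t tests.

    Adjusted p values are the raw pairwise p multiplied by the number of
    comparisons, capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs >= 2 observations")
    f_res = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    m = k * (k - 1) // 2
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            t_res = sps.ttest_ind(groups[i], groups[j], equal_var=True)
            pairwise[(i, j)] = min(float(t_res.pvalue) * m, 1.0)
    return TestResult(
        method="anova_bonferroni",
        statistic=float(f_res.statistic),
        df=(k - 1, n - k),
        p_two_sided=float(f_res.pvalue),
        effect=float(f_res.statistic),
        extra={"pairwise_p": pairwise},
    )


def linear_regression(x, y) -> TestResult:
    """OLS regression; two-sided p for slope != 0 on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.var(x) == 0:
        raise ValueError("zero x-variance: regression undefined")
    res = sps.linregress(x, y)
    return TestResult(
        method="linear_regression",
        statistic=float(res.slope / res.stderr) if res.stderr > 0 else np.inf,
        df=(x.size - 2,),
        p_two_sided=float(res.pvalue),
        effect=float(res.slope),
        extra={"intercept": float(res.intercept), "r": float(res.rvalue)},
    )
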