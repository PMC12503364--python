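"""Statistical layer: one-way ANOVA with Tukey HSD pairwise comparisons,
unpaired t-tests, and simple linear regression.

Implemented from the standard formulas (between/within sum-of-squares
decomposition, Tukey-Kramer studentized-range comparisons, pooled / Welch
t statistics, closed-form OLS); scipy supplies only the reference
distributions (F, studentized range, t) for p-values.  "Multiple
comparisons" after a one-way ANOVA is Tukey HSD — the common default of
point-and-click statistics packages — with the method name recorded in the
result so downstream tables are explicit about the correction used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupedSamples",
    "PairwiseComparison",
    "TestResult",
    "RegressionResult",
    "one_way_anova",
    "tukey_pairwise",
    "unpaired_t_test",
    "simple_linear_regression",
]


@dataclass
class GroupedSamples:
    """Labelled groups of one metric (e.g. Fe-L1 mean distance per trace)."""

    groups: list[tuple[str, np.ndarray]]
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = [(str(lbl), np.asarray(v, dtype=float)) for lbl, v in self.groups]
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for lbl, v in self.groups:
            if v.size == 0:
                raise ValueError(f"group {lbl!r} is empty")

    @property
    def labels(self) -> list[str]:
        return [lbl for lbl, _ in self.groups]

    @property
    def values(self) -> list[np.ndarray]:
        return [v for _, v in self.groups]


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    mean_difference: float
    statistic: float
    adjusted_p: float


@dataclass
class TestResult:
    method: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    p_value: float


def one_way_anova(samples: GroupedSamples) -> TestResult:
    """F = MS_between / MS_within with p from the F(k-1, N-k) distribution."""
    values = samples.values
    for lbl, v in samples.groups:
        if v.size < 2:
            raise ValueError(f"group {lbl!r} needs >= 2 values for ANOVA")
    k = len(values)
    n_total = sum(v.size for v in values)
    grand = np.concatenate(values).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in values)
    df_between = k - 1
    df_within = n_total - k
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ss_between == 0.0:
            raise ValueError("zero within-group variance with identical means: F undefined")
        f_stat = np.inf
        p = 0.0
    else:
        f_stat = (ss_between / df_between) / ms_within
        p = float(sps.f.sf(f_stat, df_between, df_within))
    return TestResult(
        method="one-way ANOVA",
        statistic=float(f_stat),
        df=(float(df_between), float(df_within)),
        p_value=p,
    )


def tukey_pairwise(samples: GroupedSamples) -> TestResult:
    """Tukey HSD (Tukey-Kramer for unequal n) adjusted pairwise comparisons.

    For each pair: q = |mean_i - mean_j| / sqrt(MS_within/2 x (1/n_i + 1/n_j)),
    adjusted p from the studentized-range distribution with k groups and
    N - k error degrees of freedom.
    """
    anova = one_way_anova(samples)
    values = samples.values
    labels = samples.labels
    k = len(values)
    n_total = sum(v.size for v in values)
    df_err = n_total - k
    ms_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in values) / df_err
    pairs: list[PairwiseComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(values[i].mean() - values[j].mean())
            se = np.sqrt(ms_within / 2.0 * (1.0 / values[i].size + 1.0 / values[j].size))
            if se == 0.0:
                q = 0.0 if diff == 0.0 else np.inf
            else:
                q = abs(diff) / se
            p_adj = float(np.clip(sps.studentized_range.sf(q, k, df_err), 0.0, 1.0))
            pairs.append(PairwiseComparison((labels[i], labels[j]), diff, float(q), p_adj))
    return TestResult(
        method="one-way ANOVA + Tukey HSD",
        statistic=anova.statistic,
        df=anova.df,
        p_value=anova.p_value,
        pairwise=pairs,
    )


def unpaired_t_test(a, b, *, welch: bool = False) -> TestResult:
    """Two-sided unpaired t-test; Student (pooled variance) by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if var_a == 0.0 and var_b == 0.0 and diff == 0.0:
        raise ValueError("zero variance in both samples with equal means: t undefined")
    if welch:
        se2 = var_a / a.size + var_b / b.size
        df = se2**2 / (
            (var_a / a.size) ** 2 / (a.size - 1) + (var_b / b.size) ** 2 / (b.size - 1)
        )
        method = "Welch unpaired t-test"
    else:
        pooled = ((a.size - 1) * var_a + (b.size - 1) * var_b) / (a.size + b.size - 2)
        se2 = pooled * (1.0 / a.size + 1.0 / b.size)
        df = a.size + b.size - 2
        method = "Student unpaired t-test"
    t = diff / np.sqrt(se2) if se2 > 0 else np.inf * np.sign(diff)
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TestResult(method=method, statistic=float(t), df=(float(df),), p_value=p)


def simple_linear_regression(x, y) -> RegressionResult:
    """Closed-form OLS fit y = slope x + intercept with r^2 and slope SE."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("need >= 3 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("x values are all equal: slope undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    df = x.size - 2
    mse = ss_res / df if df > 0 else 0.0
    slope_se = float(np.sqrt(mse / sxx))
    if slope_se > 0:
        t = slope / slope_se
        p = float(2.0 * sps.t.sf(abs(t), df))
    else:
        p = 0.0 if slope != 0.0 else 1.0
    return RegressionResult(slope, intercept, r2, slope_se, p)
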