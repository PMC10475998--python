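"""Statistical comparison layer for the quantification outputs.

The battery mirrors common practice for synapse quantification studies:
a Shapiro-Wilk normality gate routing to either parametric (pooled-variance
two-sample t, one-way ANOVA with Tukey HSD, two-way ANOVA) or
non-parametric (Mann-Whitney U) tests; a Pearson chi-squared test of
association (no continuity correction) for containment contingency tables;
and control-normalized percentage transforms for display.

Every test records the statistical unit (animal, synapse or cluster) it was
run on, because quantification studies mix animal-level and pooled
object-level comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["GroupSample", "StatTestResult", "two_sample_t", "mann_whitney_u",
           "one_way_anova_tukey", "two_way_anova",
           "chi_squared_association", "shapiro_wilk_gate",
           "normalize_to_control"]


@dataclass(frozen=True)
class GroupSample:
    """A labelled sample of measurements with its statistical unit."""

    label: str
    values: np.ndarray
    unit: str = "animal"      # animal | synapse | cluster

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if len(self.values) < 1:
            raise ValueError("GroupSample needs n >= 1")


@dataclass(frozen=True)
class StatTestResult:
    test_name: str
    statistic: float
    df: float | tuple
    p_value: float
    effect_direction: str = ""      # e.g. "a>b", "a<b", "none"
    unit: str = ""
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {"test": self.test_name, "statistic": self.statistic,
                "df": self.df, "p": self.p_value, "unit": self.unit,
                "direction": self.effect_direction}


def _direction(label_a, label_b, mean_a, mean_b) -> str:
    if mean_a > mean_b:
        return f"{label_a}>{label_b}"
    if mean_a < mean_b:
        return f"{label_a}<{label_b}"
    return "none"


def two_sample_t(a: GroupSample, b: GroupSample) -> StatTestResult:
    """Pooled-variance two-sided two-sample t test (df = n_a + n_b - 2).

    When both groups have zero variance, p is 1 for equal means and 0
    otherwise (degenerate-data convention).
    """
    if len(a.values) < 2 or len(b.values) < 2:
        raise ValueError("two_sample_t needs n >= 2 per group")
    df = len(a.values) + len(b.values) - 2
    va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
    ma, mb = a.values.mean(), b.values.mean()
    if va == 0 and vb == 0:
        t = 0.0 if ma == mb else math.inf * np.sign(ma - mb)
        p = 1.0 if ma == mb else 0.0
    else:
        t, p = sps.ttest_ind(a.values, b.values, equal_var=True)
        t, p = float(t), float(p)
    return StatTestResult("two_sample_t", t, float(df), p,
                          _direction(a.label, b.label, ma, mb), a.unit)


def _mwu_exact_feasible(x: np.ndarray, y: np.ndarray) -> bool:
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    return no_ties and len(x) * len(y) <= 400


def mann_whitney_u(a: GroupSample, b: GroupSample) -> StatTestResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p-value (full enumeration of the null distribution) when
    n_a * n_b <= 400 and there are no ties; otherwise the normal
    approximation with tie correction.  The reported U is the statistic of
    the first sample.
    """
    x, y = a.values, b.values
    method = "exact" if _mwu_exact_feasible(x, y) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatTestResult("mann_whitney_u", float(res.statistic),
                          float(len(x) * len(y)), float(res.pvalue),
                          _direction(a.label, b.label, np.median(x),
                                     np.median(y)),
                          a.unit, extra={"method": method})


def one_way_anova_tukey(groups: Sequence[GroupSample]
                        ) -> tuple[StatTestResult, pd.DataFrame]:
    """One-way ANOVA F test plus a pairwise Tukey HSD table.

    Returns the omnibus result and a tidy frame with one row per group
    pair (q-derived statistic and studentized-range adjusted p).  All
    within-group variances zero with differing means yields an infinite-F
    sentinel.
    """
    if len(groups) < 3:
        raise ValueError("one_way_anova_tukey needs >= 3 groups")
    if any(len(g.values) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    data = [g.values for g in groups]
    k = len(data)
    n_tot = sum(len(d) for d in data)
    df_b, df_w = k - 1, n_tot - k
    grand = np.concatenate(data).mean()
    ss_b = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
    ss_w = sum(((d - d.mean()) ** 2).sum() for d in data)
    if ss_w == 0:
        f = 0.0 if ss_b == 0 else math.inf
        p = 1.0 if ss_b == 0 else 0.0
    else:
        f = (ss_b / df_b) / (ss_w / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    omnibus = StatTestResult("one_way_anova", float(f), (df_b, df_w), p,
                             unit=groups[0].unit)

    rows = []
    if math.isfinite(f) and ss_w > 0:
        hsd = sps.tukey_hsd(*data)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append({
                    "group_a": groups[i].label, "group_b": groups[j].label,
                    "mean_diff": data[i].mean() - data[j].mean(),
                    "statistic": float(hsd.statistic[i, j]),
                    "p_adj": float(hsd.pvalue[i, j]),
                })
    tukey = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff",
                                        "statistic", "p_adj"])
    return omnibus, tukey


def two_way_anova(values, factor_a, factor_b,
                  names: tuple[str, str] = ("genotype", "structure"),
                  include_interaction: bool = True,
                  unit: str = "animal") -> dict[str, StatTestResult]:
    """Two-way ANOVA with Type II sums of squares (handles unbalance).

    Returns a result per effect (both main effects and, when requested, the
    interaction).  An empty factor-level cell raises a design error.  A
    constant response yields F = 0 for every effect.
    """
    df = pd.DataFrame({"y": np.asarray(values, float),
                       "fa": np.asarray(factor_a),
                       "fb": np.asarray(factor_b)})
    cells = df.groupby(["fa", "fb"], observed=True).size()
    n_a, n_b = df["fa"].nunique(), df["fb"].nunique()
    if n_a < 2 or n_b < 2:
        raise ValueError("each factor needs >= 2 levels")
    if len(cells) < n_a * n_b:
        raise ValueError("empty factor cell: unsupported design")

    if df["y"].nunique() == 1:
        out = {}
        keys = [names[0], names[1]] + (
            [f"{names[0]}:{names[1]}"] if include_interaction else [])
        for key in keys:
            out[key] = StatTestResult(f"two_way_anova[{key}]", 0.0,
                                      math.nan, 1.0, unit=unit)
        return out

    formula = "y ~ C(fa) * C(fb)" if include_interaction else \
        "y ~ C(fa) + C(fb)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    resid_df = float(table.loc["Residual", "df"])
    mapping = {"C(fa)": names[0], "C(fb)": names[1],
               "C(fa):C(fb)": f"{names[0]}:{names[1]}"}
    out = {}
    for src, name in mapping.items():
        if src not in table.index:
            continue
        f = float(table.loc[src, "F"])
        p = float(table.loc[src, "PR(>F)"])
        if math.isnan(f):
            f, p = 0.0, 1.0
        out[name] = StatTestResult(
            f"two_way_anova[{name}]", f,
            (float(table.loc[src, "df"]), resid_df), p, unit=unit,
            extra={"sum_sq": float(table.loc[src, "sum_sq"])})
    return out


def chi_squared_association(table) -> StatTestResult:
    """Pearson chi-squared test of association, no continuity correction.

    ``table`` is an r x c array of non-negative counts (or a DataFrame).
    A zero expected count in any cell makes the statistic undefined: a
    NaN sentinel is returned with a warning.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("need a 2D table of non-negative counts, total > 0")
    r, c = counts.shape
    dof = (r - 1) * (c - 1)
    expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
    if np.any(expected == 0):
        warnings.warn("zero expected count: chi-squared undefined")
        return StatTestResult("chi_squared", math.nan, float(dof), math.nan,
                              unit="object")
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, dof))
    return StatTestResult("chi_squared", chi2, float(dof), p, unit="object")


def shapiro_wilk_gate(sample, alpha: float = 0.05
                      ) -> tuple[str, StatTestResult]:
    """Normality gate routing to parametric or non-parametric tests.

    Returns ``("parametric", result)`` when the Shapiro-Wilk p-value is
    >= alpha, else ``("nonparametric", result)``.  Samples with n < 3
    cannot be tested and route non-parametric with a warning.
    """
    x = np.asarray(sample, float)
    if len(x) < 3:
        warnings.warn("n < 3: Shapiro-Wilk not defined, routing "
                      "nonparametric")
        return "nonparametric", StatTestResult("shapiro_wilk", math.nan,
                                               float(len(x)), math.nan)
    w, p = sps.shapiro(x)
    res = StatTestResult("shapiro_wilk", float(w), float(len(x)), float(p))
    return ("parametric" if p >= alpha else "nonparametric"), res


def normalize_to_control(values_condition, values_control) -> np.ndarray:
    """Express condition values as percentages of the control mean.

    The control group maps to mean 100%.  A zero (or non-positive) control
    mean leaves the percentage undefined: NaNs with a warning.
    """
    cond = np.asarray(values_condition, float)
    ctrl = np.asarray(values_control, float)
    m = ctrl.mean()
    if not np.isfinite(m) or m <= 0:
        warnings.warn("control mean <= 0: normalization undefined")
        return np.full(cond.shape, math.nan)
    return cond * 100.0 / m
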