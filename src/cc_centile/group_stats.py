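"""Inferential chain for the case/control width comparison.

Normality screening (Shapiro–Wilk), paired t-tests of the global
measures (area, perimeter, centreline length), Bonferroni-corrected
per-centile comparisons with 95% CI profiles of the group means, and
one-way ANOVA of the regional factor scores at the 95% level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CCError, CCWarning
from .synthetic import CohortWidths

__all__ = [
    "GlobalComparison",
    "CentileComparison",
    "FactorAnova",
    "shapiro_wilk",
    "paired_t",
    "centile_comparison",
    "anova_factor_scores",
]


@dataclass
class GlobalComparison:
    """Paired t-test of one global measure between groups."""
    measure: str
    t: float
    p: float
    mean_difference: float
    ci_low: float
    ci_high: float
    n_pairs: int


@dataclass
class CentileComparison:
    """Per-centile group comparison with Bonferroni control at m = 99."""
    mean_difference: np.ndarray       # (99,) case minus control, mm
    case_mean: np.ndarray             # (99,)
    case_ci: np.ndarray               # (99, 2) 95% CI of the case mean
    control_mean: np.ndarray
    control_ci: np.ndarray
    p_unadjusted: np.ndarray          # (99,)
    significant_unadjusted: np.ndarray  # p < alpha
    significant_bonferroni: np.ndarray  # p < alpha / 99
    alpha: float
    max_abs_difference: float
    argmax_centile: int               # 1-based


@dataclass
class FactorAnova:
    """One-way ANOVA of the factor scores, one row per retained factor."""
    F: np.ndarray                     # (k,)
    p: np.ndarray
    group_means: np.ndarray           # (k, 2) case, control
    critical_F: float
    df: tuple[int, int]
    alpha: float = 0.05
    significant: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.significant is None:
            self.significant = np.asarray(self.p) < self.alpha


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p for a univariate sample (3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise CCError("too-few", "Shapiro-Wilk needs at least 3 values")
    if len(x) > 5000:
        raise CCError("too-many", "Shapiro-Wilk valid up to n = 5000")
    if np.ptp(x) == 0:
        raise CCError("degenerate", "all values identical; W undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def paired_t(case_values, control_values, pairing=None,
             measure: str = "measure", alpha: float = 0.05) -> GlobalComparison:
    """Two-sided paired Student t-test with a CI of the mean difference.

    ``pairing`` optionally gives the match index of each element in both
    vectors; otherwise elements are paired positionally.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if pairing is not None:
        pa, pb = np.asarray(pairing[0]), np.asarray(pairing[1])
        a, b = a[np.argsort(pa)], b[np.argsort(pb)]
    if len(a) != len(b):
        raise CCError("bad-pairing", "groups must pair one-to-one")
    n = len(a)
    if n < 2:
        raise CCError("too-few", "paired t needs at least 2 pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return GlobalComparison(measure, 0.0, 1.0, 0.0, 0.0, 0.0, n)
        warnings.warn("zero variance of paired differences with nonzero "
                      "mean; p reported as 0", CCWarning)
        return GlobalComparison(measure, np.inf if md > 0 else -np.inf,
                                0.0, md, md, md, n)
    se = sd / np.sqrt(n)
    t = md / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    tq = stats.t.ppf(1 - alpha / 2, df=n - 1)
    return GlobalComparison(measure, float(t), float(p), md,
                            md - tq * se, md + tq * se, n)


def _group_ci(x: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean and t-based CI of the mean, per column."""
    n = len(x)
    m = x.mean(axis=0)
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    tq = stats.t.ppf(1 - alpha / 2, df=n - 1)
    return m, np.column_stack([m - tq * se, m + tq * se])


def centile_comparison(cohort: CohortWidths,
                       alpha: float = 0.05) -> CentileComparison:
    """99 per-centile group comparisons with Bonferroni threshold α/99.

    Uses the paired t-test when the cohort carries a case↔control
    pairing (the age-matched design), Welch's t otherwise.
    """
    cases, controls = cohort.split()
    if len(cases) < 2 or len(controls) < 2:
        raise CCError("too-few", "need >= 2 subjects per group")
    cm, cci = _group_ci(cases, alpha)
    km, kci = _group_ci(controls, alpha)
    diff = cm - km

    if cohort.pairing is not None and len(cases) == len(controls):
        d = cases - controls
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = d.mean(axis=0) / (sd / np.sqrt(len(d)))
        p = 2.0 * stats.t.sf(np.abs(t), df=len(d) - 1)
        p = np.where(sd == 0, np.where(d.mean(axis=0) == 0, 1.0, 0.0), p)
    else:
        _, p = stats.ttest_ind(cases, controls, axis=0, equal_var=False)

    sig_un = p < alpha
    sig_bf = p < alpha / 99.0
    k = int(np.argmax(np.abs(diff)))
    return CentileComparison(
        mean_difference=diff, case_mean=cm, case_ci=cci,
        control_mean=km, control_ci=kci, p_unadjusted=p,
        significant_unadjusted=sig_un, significant_bonferroni=sig_bf,
        alpha=alpha, max_abs_difference=float(np.abs(diff[k])),
        argmax_centile=k + 1)


def anova_factor_scores(scores: np.ndarray, groups,
                        alpha: float = 0.05) -> FactorAnova:
    """One-way between-group ANOVA of each factor-score column.

    F = MS_between / MS_within with df (1, n − 2); the critical F at the
    95% level is reported for the realized degrees of freedom.  A factor
    with zero within-group variance but distinct means yields F = +inf
    with a warning.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    if S.ndim != 2:
        raise CCError("bad-scores", "scores must be subjects x factors")
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise CCError("bad-groups", "one-way ANOVA here expects 2 groups")
    a, b = S[g == labels[0]], S[g == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise CCError("too-few", "need >= 2 subjects per group")
    n = len(a) + len(b)
    grand = S.mean(axis=0)
    ssb = len(a) * (a.mean(axis=0) - grand) ** 2 \
        + len(b) * (b.mean(axis=0) - grand) ** 2
    ssw = ((a - a.mean(axis=0)) ** 2).sum(axis=0) \
        + ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    df = (1, n - 2)
    msb = ssb / df[0]
    msw = ssw / df[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    if np.any((msw == 0) & (msb > 0)):
        warnings.warn("zero within-group variance; F reported as +inf",
                      CCWarning)
        F = np.where((msw == 0) & (msb > 0), np.inf, F)
    F = np.where((msw == 0) & (msb == 0), 0.0, F)
    p = stats.f.sf(F, *df)
    p = np.where(np.isinf(F), 0.0, p)
    # order of labels: case first when present
    if "case" in labels:
        means = np.column_stack([
            S[g == "case"].mean(axis=0), S[g != "case"].mean(axis=0)])
    else:
        means = np.column_stack([a.mean(axis=0), b.mean(axis=0)])
    return FactorAnova(F=np.asarray(F, dtype=float), p=np.asarray(p, dtype=float),
                       group_means=means,
                       critical_F=float(stats.f.ppf(1 - alpha, *df)),
                       df=df, alpha=alpha)
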