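"""Group-comparison statistics: contingency tables with adjusted-residual
post hocs, one-way ANOVA (raw or from summary statistics), one-way MANOVA
via Wilks' lambda with Rao's F approximation, Welch pairwise comparisons
under Benjamini-Hochberg FDR control, and the effect sizes tying them
together (Cramér's V, eta-squared, Cohen's d).

The test statistics are computed directly from their defining formulas
(cross-product matrices, O/E decompositions); only the reference
distributions (chi-square, F, t, normal) come from scipy.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, GROUPS

__all__ = [
    "ContingencyResult",
    "AnovaResult",
    "ManovaResult",
    "PairwiseResult",
    "CorrelationResult",
    "StatsError",
    "chi_square_test",
    "adjusted_residuals",
    "oneway_anova",
    "anova_from_summary",
    "manova_wilks",
    "pairwise_comparisons",
    "benjamini_hochberg",
    "cohens_d_pairwise",
    "eta2_to_d",
    "pearson_correlation",
]


class StatsError(ValueError):
    pass


def eta2_to_d(eta2: float) -> float:
    """Convert (multivariate) eta-squared to Cohen's d via d = 2f,
    f = sqrt(eta2 / (1 - eta2))."""
    if not 0.0 <= eta2 < 1.0:
        raise StatsError(f"eta2 must be in [0, 1), got {eta2}")
    return 2.0 * math.sqrt(eta2 / (1.0 - eta2))


# --------------------------------------------------------------------------
# contingency tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p: float
    cramers_v: float
    expected: np.ndarray = field(compare=False)
    adjusted_residuals: np.ndarray = field(compare=False)
    residual_p: np.ndarray = field(compare=False)
    posthoc_flags: np.ndarray = field(compare=False)
    alpha: float = 0.05


def _check_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise StatsError(f"need a 2-D table with ≥2 rows/cols, got {t.shape}")
    if (t < 0).any():
        raise StatsError("counts must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise StatsError("counts must be integers")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise StatsError(
            "zero row or column marginal; collapse categories upstream")
    return t


def adjusted_residuals(table, alpha: float = 0.05,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized adjusted cell residuals and Bonferroni post-hoc flags.

    r_ij = (O - E) / sqrt(E (1 - row_i/N) (1 - col_j/N)); each residual
    gets a two-sided normal p, flagged when p < alpha / (rows * cols).
    Returns (residuals, cell p-values, flags).
    """
    t = _check_table(table)
    N = t.sum()
    r = t.sum(axis=1, keepdims=True)
    c = t.sum(axis=0, keepdims=True)
    E = r @ c / N
    denom = np.sqrt(E * (1.0 - r / N) * (1.0 - c / N))
    resid = (t - E) / denom
    pvals = 2.0 * stats.norm.sf(np.abs(resid))
    flags = pvals < alpha / t.size
    return resid, pvals, flags


def chi_square_test(table, alpha: float = 0.05) -> ContingencyResult:
    """Pearson chi-square test of independence with Cramér's V and
    adjusted-residual post hocs."""
    t = _check_table(table)
    N = t.sum()
    E = t.sum(axis=1, keepdims=True) @ t.sum(axis=0, keepdims=True) / N
    chi2 = float(((t - E) ** 2 / E).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    v = math.sqrt(chi2 / (N * (min(t.shape) - 1)))
    resid, pvals, flags = adjusted_residuals(t, alpha=alpha)
    return ContingencyResult(chi2=chi2, df=df, p=p, cramers_v=v, expected=E,
                             adjusted_residuals=resid, residual_p=pvals,
                             posthoc_flags=flags, alpha=alpha)


# --------------------------------------------------------------------------
# ANOVA / MANOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta2: float
    d: float


def anova_from_summary(ns, means, sds) -> AnovaResult:
    """One-way ANOVA from group sizes, means and sample SDs.

    SSb = sum n_i (m_i - grand)^2 with the n-weighted grand mean;
    SSw = sum (n_i - 1) s_i^2.  Identical floating-point decomposition
    to :func:`oneway_anova` on raw data, so the two agree exactly.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (len(ns) == len(means) == len(sds)):
        raise StatsError("ns, means, sds must have equal length")
    if len(ns) < 2:
        raise StatsError("need at least 2 groups")
    if (ns < 2).any():
        raise StatsError("every group needs n ≥ 2")
    if (sds < 0).any():
        raise StatsError("sds must be non-negative")
    N = ns.sum()
    k = len(ns)
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    df_b, df_w = k - 1, int(N) - k
    if ssw == 0.0:
        raise StatsError("zero within-group variance")
    F = (ssb / df_b) / (ssw / df_w)
    eta2 = ssb / (ssb + ssw)
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w,
                       p=float(stats.f.sf(F, df_b, df_w)),
                       eta2=float(eta2), d=eta2_to_d(eta2))


def _split_groups(values, groups) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in GROUPS if (groups == g).any()]
    if not labels:  # arbitrary labels are fine too
        labels = list(pd.unique(groups))
    return [values[groups == g] for g in labels]


def oneway_anova(values, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA on raw per-participant values."""
    samples = _split_groups(values, groups)
    if len(samples) < 2:
        raise StatsError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise StatsError("every group needs at least 2 values")
    ns = [len(s) for s in samples]
    means = [float(s.mean()) for s in samples]
    sds = [float(s.std(ddof=1)) for s in samples]
    return anova_from_summary(ns, means, sds)


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    F_approx: float
    df1: float
    df2: float
    p: float
    eta2: float
    d: float
    df_design: int  # k - 1, the design (hypothesis) degrees of freedom


def manova_wilks(response_matrix, groups) -> ManovaResult:
    """One-way MANOVA: Wilks' lambda with Rao's F approximation.

    Lambda = det(E) / det(E + H) from the within-group (E) and
    between-group (H) cross-product matrices.  Multivariate eta-squared
    is 1 - Lambda^(1/s) and d = 2 sqrt(eta2/(1-eta2)).
    """
    X = np.asarray(response_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    groups = np.asarray(groups)
    if len(groups) != X.shape[0]:
        raise StatsError("groups length must match response rows")
    labels = pd.unique(groups)
    k = len(labels)
    n_obs, p = X.shape
    if k < 2:
        raise StatsError("need at least 2 groups")
    if n_obs - k <= p - 1:
        raise StatsError("too few observations for the number of measures")
    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for g in labels:
        sub = X[groups == g]
        diff = sub.mean(axis=0) - grand
        H += len(sub) * np.outer(diff, diff)
        centered = sub - sub.mean(axis=0)
        E += centered.T @ centered
    sign, logdet_E = np.linalg.slogdet(E)
    if sign <= 0:
        raise StatsError(
            "singular within-group cross-product matrix (collinear "
            "measures); remove redundant measures")
    _, logdet_T = np.linalg.slogdet(E + H)
    lam = float(np.exp(logdet_E - logdet_T))
    vh = k - 1  # hypothesis df
    ve = n_obs - k  # error df
    if p * p + vh * vh - 5 > 0:
        s = math.sqrt((p * p * vh * vh - 4.0) / (p * p + vh * vh - 5.0))
    else:
        s = 1.0
    df1 = p * vh
    df2 = s * (ve + vh - (p + vh + 1) / 2.0) - (p * vh - 2) / 2.0
    lam_s = lam ** (1.0 / s)
    F = ((1.0 - lam_s) / lam_s) * (df2 / df1)
    eta2 = 1.0 - lam_s
    return ManovaResult(wilks_lambda=lam, F_approx=float(F), df1=float(df1),
                        df2=float(df2), p=float(stats.f.sf(F, df1, df2)),
                        eta2=float(eta2), d=eta2_to_d(eta2),
                        df_design=vh)


# --------------------------------------------------------------------------
# pairwise comparisons, FDR, effect sizes, correlation
# --------------------------------------------------------------------------

def cohens_d_pairwise(a, b) -> float:
    """Cohen's d with the (n-1)-weighted pooled SD; sign follows
    mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs n ≥ 2")
    na, nb = len(a), len(b)
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                       / (na + nb - 2))
    if pooled == 0.0:
        raise StatsError("zero pooled SD")
    return float((a.mean() - b.mean()) / pooled)


def benjamini_hochberg(pvalues, q: float = 0.05,
                       ) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up FDR procedure.

    Sort ascending, find k* = max{k : p_(k) <= (k/m) q}, reject every
    p <= p_(k*).  Returns (rejection flags in input order, the realized
    p criterion p_(k*), 0 when nothing is rejected).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if ((p < 0) | (p > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise StatsError(f"q must be in (0, 1), got {q}")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ks = np.flatnonzero(sorted_p <= (np.arange(1, m + 1) / m) * q)
    if ks.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    crit = float(sorted_p[ks[-1]])
    return p <= crit, crit


@dataclass(frozen=True)
class PairwiseResult:
    measure: str
    pair: tuple[str, str]
    mean_diff: float
    t: float
    p: float
    d: float
    significant: bool = False


def pairwise_comparisons(cohort: CohortTable, measures=None,
                         q: float = 0.05, welch: bool = True,
                         ) -> tuple[list[PairwiseResult], float]:
    """All measure x group-pair comparisons with family-wide BH control.

    Welch (unequal-variance) t-tests by default; Cohen's d always uses
    the pooled SD.  The BH family is every comparison jointly (21
    measures x 6 pairs = 126 at the full battery).  Returns the result
    list and the realized BH p criterion.
    """
    if measures is None:
        measures = cohort.battery.measure_names
    groups = [g for g in GROUPS if (cohort.groups == g).any()]
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    results: list[PairwiseResult] = []
    for m in measures:
        cohort.battery.measure(m)
        for ga, gb in itertools.combinations(groups, 2):
            a = cohort.group_subset(ga)[m].dropna().to_numpy()
            b = cohort.group_subset(gb)[m].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                raise StatsError(
                    f"measure {m!r}: group pair ({ga}, {gb}) has < 2 values")
            tt = stats.ttest_ind(a, b, equal_var=not welch)
            results.append(PairwiseResult(
                measure=m, pair=(ga, gb),
                mean_diff=float(a.mean() - b.mean()),
                t=float(tt.statistic), p=float(tt.pvalue),
                d=cohens_d_pairwise(a, b)))
    flags, crit = benjamini_hochberg([r.p for r in results], q=q)
    results = [PairwiseResult(r.measure, r.pair, r.mean_diff, r.t, r.p, r.d,
                              significant=bool(f))
               for r, f in zip(results, flags)]
    return results, crit


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson correlation with pairwise-complete deletion and t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise StatsError("need at least 3 complete pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise StatsError("zero variance in x or y")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p)
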