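"""Group-difference inference: mixed ANOVA with sphericity handling, contrasts
against the whole sample, paired tests, chi-squared utilities and noncentral-F
power computations.

The mixed (split-plot) ANOVA has one between-subject factor (cluster group)
and one within-subject factor (behavioural domain); Mauchly's W tests
sphericity of the pooled within-group covariance and Greenhouse-Geisser
epsilon deflates the within-subject degrees of freedom when it is violated.

The power routines follow a fixed-effects one-way convention in which the
domain count m is the numerator df (equivalently m + 1 design cells):
numerator df = m, denominator df = N - m - 1, noncentrality lambda = f^2 * N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class EffectResult:
    F: float
    df1: float
    df2: float
    p: float
    df1_gg: float | None = None
    df2_gg: float | None = None
    p_gg: float | None = None


@dataclass
class AnovaResult:
    group: EffectResult
    domain: EffectResult
    interaction: EffectResult
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    epsilon: float
    flags: dict


def _orthonormal_contrasts(m: int) -> np.ndarray:
    """(m-1) x m orthonormal contrast matrix (Helmert, normalised)."""
    C = np.zeros((m - 1, m))
    for i in range(m - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1.0)
        C[i] /= np.linalg.norm(C[i])
    return C


def rm_anova(scores: np.ndarray, group: np.ndarray) -> AnovaResult:
    """Mixed-design ANOVA: between-subject group, within-subject domain, interaction.

    ``scores`` is subjects x domains (complete); ``group`` a label per subject.
    """
    Y = np.asarray(scores, dtype=float)
    group = np.asarray(group)
    n, m = Y.shape
    groups, gidx = np.unique(group, return_inverse=True)
    g = groups.size
    if g < 2 or m < 2:
        raise ValueError("need >= 2 groups and >= 2 domains")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    dom_means = Y.mean(axis=0)
    group_means = np.array([subj_means[gidx == i].mean() for i in range(g)])
    n_per = np.array([(gidx == i).sum() for i in range(g)])

    ss_group = m * float(np.sum(n_per * (group_means - grand) ** 2))
    ss_subj = m * float(np.sum((subj_means - group_means[gidx]) ** 2))
    ss_dom = n * float(np.sum((dom_means - grand) ** 2))
    cell_means = np.array([Y[gidx == i].mean(axis=0) for i in range(g)])  # g x m
    ss_inter = float(
        np.sum(
            n_per[:, None]
            * (cell_means - group_means[:, None] - dom_means[None, :] + grand) ** 2
        )
    )
    ss_total = float(np.sum((Y - grand) ** 2))
    ss_err = ss_total - ss_group - ss_subj - ss_dom - ss_inter

    df_group, df_subj = g - 1, n - g
    df_dom = m - 1
    df_inter = (g - 1) * (m - 1)
    df_err = (n - g) * (m - 1)

    F_group = (ss_group / df_group) / (ss_subj / df_subj)
    F_dom = (ss_dom / df_dom) / (ss_err / df_err)
    F_inter = (ss_inter / df_inter) / (ss_err / df_err)

    # Pooled within-group covariance of the domain scores.
    flags = {}
    S = np.zeros((m, m))
    for i in range(g):
        sub = Y[gidx == i]
        if sub.shape[0] > 1:
            S += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
    S /= n - g
    C = _orthonormal_contrasts(m)
    V = C @ S @ C.T
    lam = np.linalg.eigvalsh(V)
    if lam.min() <= 0:
        flags["singular_covariance"] = True
        lam = np.clip(lam, 1e-12, None)
    eps = float(lam.sum() ** 2 / ((m - 1) * np.sum(lam**2)))
    eps = float(np.clip(eps, 1.0 / (m - 1), 1.0))

    detV = float(np.prod(lam))
    W = detV / (lam.mean() ** (m - 1))
    d_ = m - 1
    chi_mult = (2 * d_**2 + d_ + 2) / (6.0 * d_)
    mauchly_chi2 = -(df_subj - chi_mult) * np.log(max(W, 1e-300))
    mauchly_df = int(d_ * (d_ + 1) / 2 - 1)
    mauchly_p = float(stats.chi2.sf(mauchly_chi2, mauchly_df))

    def effect(F, df1, df2, gg: bool) -> EffectResult:
        res = EffectResult(
            F=float(F), df1=float(df1), df2=float(df2), p=float(stats.f.sf(F, df1, df2))
        )
        if gg:
            res.df1_gg = df1 * eps
            res.df2_gg = df2 * eps
            res.p_gg = float(stats.f.sf(F, res.df1_gg, res.df2_gg))
        return res

    return AnovaResult(
        group=effect(F_group, df_group, df_subj, gg=False),
        domain=effect(F_dom, df_dom, df_err, gg=True),
        interaction=effect(F_inter, df_inter, df_err, gg=True),
        mauchly_w=float(W),
        mauchly_chi2=float(mauchly_chi2),
        mauchly_df=mauchly_df,
        mauchly_p=mauchly_p,
        epsilon=eps,
        flags=flags,
    )


def contrast_vs_sample(scores: np.ndarray, labels: np.ndarray, factor_index: int,
                       n_factors_tested: int | None = None) -> dict:
    """One-sample t of each cluster against the whole-sample mean on one factor.

    Bonferroni adjusts across the number of factors tested (defaults to the
    number of score columns).
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    col = X[:, factor_index]
    sample_mean = col.mean()
    sample_sd = col.std(ddof=1)
    m = X.shape[1] if n_factors_tested is None else n_factors_tested
    out = {}
    for c in np.unique(labels):
        vals = col[labels == c]
        if vals.size < 2:
            out[int(c)] = {"t": np.nan, "p_adj": np.nan, "d": np.nan, "flag": "singleton"}
            continue
        t, p = stats.ttest_1samp(vals, sample_mean)
        out[int(c)] = {
            "t": float(t),
            "p_raw": float(p),
            "p_adj": float(min(1.0, p * m)),
            "d": float((vals.mean() - sample_mean) / sample_sd),
        }
    return out


def paired_ttest(x_w1: np.ndarray, x_w2: np.ndarray) -> tuple[float, int, float, float]:
    """Paired t-test with Cohen's d = mean(diff)/SD(diff); satisfies d = t/sqrt(n)."""
    a = np.asarray(x_w1, dtype=float)
    b = np.asarray(x_w2, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 matched pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    n = diff.size
    d = diff.mean() / sd
    t = d * np.sqrt(n)
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p), float(d)


def chi2_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table."""
    T = np.asarray(table, dtype=float)
    if T.sum() <= 0:
        raise ValueError("table total must be positive")
    rows = T.sum(axis=1) > 0
    cols = T.sum(axis=0) > 0
    T = T[np.ix_(rows, cols)]
    r, c = T.shape
    expected = np.outer(T.sum(axis=1), T.sum(axis=0)) / T.sum()
    stat = float(np.sum((T - expected) ** 2 / expected))
    df = (r - 1) * (c - 1)
    return stat, df, float(stats.chi2.sf(stat, df)) if df > 0 else 1.0


def chi2_sf(value: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if value < 0 or df < 1:
        raise ValueError("need value >= 0 and df >= 1")
    return float(stats.chi2.sf(value, df))


def anova_power(f: float, domains: int, n: int, alpha: float = 0.05) -> float:
    """Noncentral-F power of a fixed-effects ANOVA with ``domains`` numerator df.

    Convention: numerator df = number of factor domains m (i.e. m + 1 design
    cells), denominator df = N - m - 1, noncentrality lambda = f^2 * N.
    """
    df1 = domains
    df2 = n - domains - 1
    if df2 <= 0:
        return 0.0
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, f * f * n))


def anova_min_n(f: float, domains: int, alpha: float = 0.05, power: float = 0.95) -> int:
    """Smallest total N whose ANOVA power (see :func:`anova_power`) reaches ``power``."""
    if f <= 0 or domains < 1:
        raise ValueError("need f > 0 and domains >= 1")
    lo, hi = domains + 2, domains + 3
    while anova_power(f, domains, hi, alpha) < power:
        hi *= 2
        if hi > 10**9:
            raise ValueError("target power unreachable")
    while lo < hi:
        mid = (lo + hi) // 2
        if anova_power(f, domains, mid, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(lo)


def anova_detectable_f(n: int, domains: int, alpha: float = 0.05, power: float = 0.95) -> float:
    """Effect size f at which a fixed-n ANOVA attains exactly ``power``."""
    if n <= domains + 1:
        raise ValueError("need n > domains + 1")
    lo, hi = 1e-6, 10.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if anova_power(mid, domains, n, alpha) >= power:
            hi = mid
        else:
            lo = mid
    return float(hi)
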