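"""Unit tests for mixed ANOVA, contrasts, chi-squared utilities and power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import helmert

from devprofiles.inference import (
    anova_detectable_f,
    anova_min_n,
    anova_power,
    chi2_independence,
    chi2_sf,
    contrast_vs_sample,
    paired_ttest,
    rm_anova,
)


def _mixed_data(seed=7, n=60, m=4, g=3):
    rng = np.random.default_rng(seed)
    groups = rng.integers(0, g, n)
    Y = (
        rng.normal(0, 1, n)[:, None]
        + rng.normal(0, 1, (n, m))
        + 0.5 * np.arange(m)
        + 0.3 * groups[:, None]
    )
    return Y, groups


# ---------------------------------------------------------------- mixed ANOVA


def test_rm_anova_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    Y, groups = _mixed_data()
    n, m = Y.shape
    res = rm_anova(Y, groups)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), m),
            "domain": np.tile(np.arange(m), n),
            "group": np.repeat(groups, m),
            "y": Y.ravel(),
        }
    )
    aov = pg.mixed_anova(df, dv="y", within="domain", between="group", subject="subject")
    ref = {r["Source"]: r for _, r in aov.iterrows()}
    assert res.group.F == pytest.approx(ref["group"]["F"], rel=1e-10)
    assert res.group.p == pytest.approx(ref["group"]["p_unc"], rel=1e-10)
    assert res.domain.F == pytest.approx(ref["domain"]["F"], rel=1e-10)
    assert res.interaction.F == pytest.approx(ref["Interaction"]["F"], rel=1e-10)
    assert (res.group.df1, res.group.df2) == (ref["group"]["DF1"], ref["group"]["DF2"])


def test_rm_anova_mauchly_and_epsilon_manual_oracle():
    Y, groups = _mixed_data(seed=11, n=40, m=5, g=2)
    Y[:, 2] *= 2.0  # break sphericity
    res = rm_anova(Y, groups)
    n, m = Y.shape
    g = np.unique(groups).size
    C = helmert(m, full=False).T
    S = np.zeros((m, m))
    for gv in np.unique(groups):
        Z = Y[groups == gv] - Y[groups == gv].mean(axis=0)
        S += Z.T @ Z
    S /= n - g
    lam = np.linalg.eigvalsh(C.T @ S @ C)
    W = np.prod(lam) / lam.mean() ** (m - 1)
    d = m - 1
    chi2 = -(n - g - (2 * d**2 + d + 2) / (6.0 * d)) * np.log(W)
    eps = lam.sum() ** 2 / ((m - 1) * np.sum(lam**2))
    assert res.mauchly_w == pytest.approx(W, rel=1e-10)
    assert res.mauchly_chi2 == pytest.approx(chi2, rel=1e-10)
    assert res.epsilon == pytest.approx(eps, rel=1e-10)
    assert res.mauchly_p < 0.05  # violation detected


def test_rm_anova_gg_dfs_scale_with_epsilon():
    Y, groups = _mixed_data(seed=12)
    res = rm_anova(Y, groups)
    eps = res.epsilon
    assert res.domain.df1_gg == pytest.approx(res.domain.df1 * eps)
    assert res.domain.df2_gg == pytest.approx(res.domain.df2 * eps)
    assert res.domain.p_gg == pytest.approx(
        stats.f.sf(res.domain.F, res.domain.df1_gg, res.domain.df2_gg)
    )
    assert 1.0 / (Y.shape[1] - 1) <= eps <= 1.0
    # Group effect has no within-subject dfs to correct.
    assert res.group.p_gg is None


def test_rm_anova_detects_domain_effect():
    rng = np.random.default_rng(13)
    Y = rng.normal(size=(80, 4))
    Y[:, 0] += 1.0
    groups = rng.integers(0, 2, 80)
    res = rm_anova(Y, groups)
    assert res.domain.p < 1e-6
    assert res.domain.p_gg < 1e-5


def test_rm_anova_rejects_degenerate_design():
    with pytest.raises(ValueError):
        rm_anova(np.zeros((10, 4)), np.zeros(10))  # one group


# ---------------------------------------------------------------- contrasts


def test_contrast_vs_sample_values():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(300, 2))
    labels = np.array([1] * 100 + [2] * 200)
    X[labels == 1, 0] += 1.5
    res = contrast_vs_sample(X, labels, 0)
    vals = X[labels == 1, 0]
    t_ref, p_ref = stats.ttest_1samp(vals, X[:, 0].mean())
    assert res[1]["t"] == pytest.approx(t_ref)
    assert res[1]["p_adj"] == pytest.approx(min(1.0, p_ref * 2))
    assert res[1]["d"] == pytest.approx(
        (vals.mean() - X[:, 0].mean()) / X[:, 0].std(ddof=1)
    )
    assert res[1]["p_adj"] < 0.001 and res[2]["p_adj"] < 0.05  # complement shifts too


def test_contrast_vs_sample_singleton_flagged():
    X = np.arange(10.0).reshape(5, 2)
    labels = np.array([1, 2, 2, 2, 2])
    res = contrast_vs_sample(X, labels, 0)
    assert res[1]["flag"] == "singleton"
    assert np.isnan(res[1]["t"])


def test_paired_ttest_d_identity():
    rng = np.random.default_rng(15)
    a = rng.normal(size=50)
    b = a + rng.normal(0.3, 1, 50)
    t, df, p, d = paired_ttest(a, b)
    assert df == 49
    assert d == pytest.approx(t / np.sqrt(50))
    t_ref, p_ref = stats.ttest_rel(a, b)
    assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)
    with pytest.raises(ValueError):
        paired_ttest(a, a)


# ---------------------------------------------------------------- chi-squared


def test_chi2_independence_hand_example():
    stat, df, p = chi2_independence(np.array([[30, 10], [10, 30]]))
    assert stat == pytest.approx(20.0)
    assert df == 1
    assert p == pytest.approx(stats.chi2.sf(20.0, 1))


def test_chi2_independence_drops_zero_margins():
    stat, df, p = chi2_independence(np.array([[30, 10, 0], [10, 30, 0]]))
    assert stat == pytest.approx(20.0) and df == 1


def test_chi2_sf_paper_values():
    assert chi2_sf(56, 49) == pytest.approx(0.229, abs=5e-4)
    assert chi2_sf(30, 25) == pytest.approx(0.224, abs=5e-4)
    assert chi2_sf(0, 3) == 1.0
    with pytest.raises(ValueError):
        chi2_sf(-1, 3)


# ---------------------------------------------------------------- power


def test_power_paper_triplet():
    assert anova_min_n(0.1, 6, 0.05, 0.95) == 2093
    assert round(anova_detectable_f(12134, 6, 0.05, 0.95), 2) == 0.04
    assert round(anova_detectable_f(6744, 6, 0.05, 0.95), 2) == 0.06


def test_power_monotonicities():
    powers = [anova_power(f, 6, 500) for f in (0.05, 0.1, 0.2, 0.4)]
    assert np.all(np.diff(powers) > 0)
    ns = [anova_min_n(f, 6) for f in (0.05, 0.1, 0.2)]
    assert np.all(np.diff(ns) < 0)


def test_power_min_n_brackets_target():
    n = anova_min_n(0.1, 6, 0.05, 0.95)
    assert anova_power(0.1, 6, n) >= 0.95 > anova_power(0.1, 6, n - 1)


def test_power_roundtrip():
    for n in (800, 3000):
        f = anova_detectable_f(n, 6, 0.05, 0.95)
        assert anova_min_n(f, 6, 0.05, 0.95) <= n
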