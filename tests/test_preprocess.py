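"""Unit tests for screening, EM imputation, KDE discretisation and outliers."""

import numpy as np
import pytest

from devprofiles.preprocess import (
    em_impute,
    kde_discretise,
    mahalanobis_cutoff,
    remove_outliers,
    screen_missing,
)
from devprofiles.ratings import RatingMatrix, analogue_items, ordinal_items


def _matrix(scores, kind="analogue"):
    scores = np.asarray(scores, dtype=float)
    meta = (
        analogue_items(scores.shape[1], -1e9, 1e9)
        if kind == "analogue"
        else ordinal_items(scores.shape[1])
    )
    return RatingMatrix(scores, meta, np.arange(1, scores.shape[0] + 1))


# ---------------------------------------------------------------- screening


def test_screen_missing_cutoff_is_strict():
    X = np.zeros((3, 10))
    X[0, :5] = np.nan  # 5 missing -> kept at max_missing=5
    X[1, :6] = np.nan  # 6 missing -> excluded
    kept, rep = screen_missing(_matrix(X), max_missing=5)
    assert list(kept.subject_ids) == [1, 3]
    assert list(rep.excluded_missing_ids) == [2]


def test_screening_report_partitions_input():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 6))
    X[rng.random(X.shape) < 0.3] = np.nan
    kept, rep = screen_missing(_matrix(X), max_missing=2)
    all_ids = set(kept.subject_ids) | set(rep.excluded_missing_ids)
    assert all_ids == set(range(1, 201))
    assert not (set(kept.subject_ids) & set(rep.excluded_missing_ids))


# ---------------------------------------------------------------- EM


def test_em_imputes_conditional_mean():
    rng = np.random.default_rng(3)
    n = 4000
    mu = np.array([1.0, -2.0])
    cov = np.array([[1.0, 0.6], [0.6, 2.0]])
    X = rng.multivariate_normal(mu, cov, size=n)
    Xm = X.copy()
    Xm[0, 1] = np.nan
    comp, mu_hat, sig_hat, _ = em_impute(_matrix(Xm))
    cond = mu_hat[1] + sig_hat[0, 1] / sig_hat[0, 0] * (X[0, 0] - mu_hat[0])
    assert comp.scores[0, 1] == pytest.approx(cond, abs=1e-6)
    assert not np.isnan(comp.scores).any()


def test_em_recovers_moments():
    rng = np.random.default_rng(4)
    cov = 0.5 * np.eye(5) + 0.5
    X = rng.multivariate_normal(np.arange(5.0), cov, size=3000)
    Xm = X.copy()
    Xm[rng.random(X.shape) < 0.15] = np.nan
    _, mu_hat, sig_hat, _ = em_impute(_matrix(Xm))
    assert np.allclose(mu_hat, np.arange(5.0), atol=0.1)
    assert np.allclose(sig_hat, cov, atol=0.15)


def test_em_beats_listwise_deletion():
    # Spec-level invariant at reduced size: EM covariance closer to the
    # complete-data covariance than listwise deletion in >= 90% of replicates.
    rng = np.random.default_rng(5)
    wins = 0
    n_rep = 50
    for _ in range(n_rep):
        L = rng.normal(size=(10, 3))
        cov = L @ L.T + np.eye(10)
        X = rng.multivariate_normal(np.zeros(10), cov, size=2000)
        full_cov = np.cov(X, rowvar=False)
        Xm = X.copy()
        Xm[rng.random(X.shape) < 0.10] = np.nan
        _, _, em_cov, _ = em_impute(_matrix(Xm))
        complete = ~np.isnan(Xm).any(axis=1)
        lw_cov = np.cov(Xm[complete], rowvar=False)
        if np.linalg.norm(em_cov - full_cov) < np.linalg.norm(lw_cov - full_cov):
            wins += 1
    assert wins >= 0.9 * n_rep


def test_em_rounds_ordinal_items():
    rng = np.random.default_rng(6)
    X = rng.integers(1, 5, size=(300, 4)).astype(float)
    X[0, 0] = np.nan
    comp, _, _, _ = em_impute(_matrix(X, kind="ordinal"))
    v = comp.scores[0, 0]
    assert v == np.round(v) and 1 <= v <= 4


def test_em_no_missing_is_identity():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(100, 3))
    comp, _, _, n_iter = em_impute(_matrix(X))
    np.testing.assert_allclose(comp.scores, X)


# ---------------------------------------------------------------- outliers


def test_mahalanobis_cutoff_paper_values():
    assert mahalanobis_cutoff(7, 0.001) == pytest.approx(24.32, abs=0.005)
    assert mahalanobis_cutoff(1, 0.001) == pytest.approx(10.828, abs=0.0005)
    cuts = [mahalanobis_cutoff(d, 0.001) for d in range(1, 12)]
    assert np.all(np.diff(cuts) > 0)
    with pytest.raises(ValueError):
        mahalanobis_cutoff(0, 0.001)
    with pytest.raises(ValueError):
        mahalanobis_cutoff(3, 1.5)


def test_remove_outliers_univariate_flag():
    rng = np.random.default_rng(8)
    X = rng.uniform(-1, 1, size=(400, 5))
    X[10, 2] = X[:, 2].mean() + 5 * X[:, 2].std(ddof=1)
    keep, rep = remove_outliers(X, np.arange(1, 401))
    assert 11 in rep.excluded_univariate_ids
    assert not keep[10]


def test_remove_outliers_multivariate_only():
    rng = np.random.default_rng(9)
    # Strongly correlated 7-dim data; break the correlation within 3 SD/coord.
    z = rng.normal(size=(600, 1))
    X = z + 0.35 * rng.normal(size=(600, 7))
    sd = X.std(axis=0, ddof=1)
    pattern = np.array([1, -1, 1, -1, 1, -1, 1]) * 2.0 * sd
    prec = np.linalg.inv(np.cov(X, rowvar=False))
    assert pattern @ prec @ pattern > 30  # premise of the spec example
    X[5] = X.mean(axis=0) + pattern
    keep, rep = remove_outliers(X, np.arange(1, 601))
    assert 6 in rep.excluded_multivariate_ids
    assert 6 not in rep.excluded_univariate_ids


def test_remove_outliers_infinite_thresholds_keep_all():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(200, 4))
    keep, rep = remove_outliers(X, np.arange(200), z_thresh=np.inf, alpha=1e-300)
    assert keep.all()


# ---------------------------------------------------------------- KDE


def test_kde_bimodal_cutpoint():
    rng = np.random.default_rng(11)
    v = np.concatenate([rng.normal(20, 5, 400), rng.normal(70, 5, 400)])
    levels, cuts, degenerate = kde_discretise(v, 2)
    assert not degenerate
    assert 35 < cuts[0] < 55
    np.testing.assert_array_equal(levels, np.where(v < cuts[0], 1, 2))


def test_kde_monotone_in_value():
    rng = np.random.default_rng(12)
    v = rng.normal(size=500)
    levels, _, _ = kde_discretise(v, 4)
    order = np.argsort(v)
    assert np.all(np.diff(levels[order]) >= 0)
    assert set(levels) <= {1, 2, 3, 4}


def test_kde_unimodal_fallback_is_quantile_binning():
    rng = np.random.default_rng(13)
    # Moderate n keeps the Silverman bandwidth wide enough that the KDE is
    # genuinely unimodal (large samples grow isolated tail bumps).
    v = rng.normal(size=200)
    levels, cuts, _ = kde_discretise(v, 3)
    # Unimodal density has no interior minima: cutpoints are the terciles.
    expected = np.quantile(v, [1 / 3, 2 / 3])
    np.testing.assert_allclose(np.sort(cuts), expected, atol=1e-8)


def test_kde_degenerate_constant_input():
    levels, cuts, degenerate = kde_discretise(np.full(50, 7.0), 4)
    assert degenerate
    assert set(levels) == {1}
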