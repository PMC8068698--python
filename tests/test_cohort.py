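"""Unit tests for the synthetic cohort generator."""

import numpy as np
import pytest

from devprofiles.cohort import (
    CohortConfig,
    GroundTruth,
    generate_cohort,
    ordinal_thresholds,
    plant_missingness,
    plant_outliers,
)
from devprofiles.preprocess import mahalanobis_cutoff
from devprofiles.ratings import RatingMatrix, analogue_items


def test_generate_is_deterministic():
    a1, a2, _ = generate_cohort(CohortConfig(n_subjects=200, seed=11))
    b1, b2, _ = generate_cohort(CohortConfig(n_subjects=200, seed=11))
    np.testing.assert_array_equal(a1.scores, b1.scores)
    np.testing.assert_array_equal(a2.scores, b2.scores)


def test_different_seeds_differ():
    a1, _, _ = generate_cohort(CohortConfig(n_subjects=200, seed=1))
    b1, _, _ = generate_cohort(CohortConfig(n_subjects=200, seed=2))
    assert not np.array_equal(a1.scores, b1.scores)


def test_wave_shapes_and_ranges(small_cohort):
    cfg, wave1, wave2, truth = small_cohort
    assert wave1.scores.shape == (cfg.n_subjects, cfg.n_items)
    assert wave2.scores.shape == (cfg.n_subjects, cfg.n_items)
    assert wave1.validate_ranges() == []
    assert wave2.validate_ranges() == []
    assert np.nanmin(wave1.scores) >= 0.0 and np.nanmax(wave1.scores) <= 100.0
    obs2 = wave2.scores[~np.isnan(wave2.scores)]
    assert set(np.unique(obs2)) <= {1.0, 2.0, 3.0, 4.0}


def test_clean_config_has_no_missing_or_outliers():
    cfg = CohortConfig(
        n_subjects=150, missing_rate=0.0, n_uni_outliers=0, n_multi_outliers=0, seed=3
    )
    wave1, wave2, truth = generate_cohort(cfg)
    w1 = plant_missingness(wave1, cfg.missing_rate, seed=3)
    w1, ids = plant_outliers(w1, cfg.n_uni_outliers, cfg.n_multi_outliers, seed=3)
    assert not w1.missing_mask.any()
    assert not wave2.missing_mask.any()
    assert ids.size == 0


def test_labels_follow_weights_and_transitions(small_cohort):
    cfg, _, _, truth = small_cohort
    w = np.asarray(cfg.cluster_weights_w1)
    counts = np.bincount(truth.labels_w1, minlength=w.size)
    # Multinomial draw: each share within 4 standard errors of its weight.
    n = counts.sum()
    se = np.sqrt(w * (1 - w) / n)
    assert np.all(np.abs(counts / n - w) < 4 * se + 1e-12)
    tm = np.asarray(cfg.transition_matrix)
    # Conditional wave-2 distribution follows the planted transition row.
    for i in range(tm.shape[0]):
        sel = truth.labels_w1 == i
        if sel.sum() < 30:
            continue
        obs = np.bincount(truth.labels_w2[sel], minlength=tm.shape[1]) / sel.sum()
        se_row = np.sqrt(tm[i] * (1 - tm[i]) / sel.sum())
        assert np.all(np.abs(obs - tm[i]) < 4 * se_row + 1e-12)


def test_latent_scores_match_prototypes(small_cohort):
    cfg, _, _, truth = small_cohort
    protos = np.asarray(cfg.cluster_prototypes_w1)
    for c in range(protos.shape[0]):
        sel = truth.labels_w1 == c
        if sel.sum() < 30:
            continue
        centre = truth.latent_scores_w1[sel].mean(axis=0)
        assert np.allclose(centre, protos[c], atol=4 * cfg.noise_sd / np.sqrt(sel.sum()) + 0.05)


def test_missingness_rate_and_determinism(small_cohort):
    _, wave1, _, _ = small_cohort
    out1 = plant_missingness(wave1, 0.05, seed=9)
    out2 = plant_missingness(wave1, 0.05, seed=9)
    np.testing.assert_array_equal(out1.missing_mask, out2.missing_mask)
    rate = out1.missing_mask.mean()
    assert abs(rate - 0.05) < 0.01
    assert not wave1.missing_mask.any()  # input untouched


def test_plant_single_univariate_outlier():
    rng = np.random.default_rng(0)
    # Uniform scores are bounded (max |z| ~ 1.73), so only the planted cell
    # can lie beyond 3 SD.
    X = rng.uniform(40, 60, size=(300, 8))
    m = RatingMatrix(X, analogue_items(8, 0, 200), np.arange(300))
    out, ids = plant_outliers(m, n_uni=1, n_multi=0, seed=4)
    z = (out.scores - out.scores.mean(axis=0)) / out.scores.std(axis=0, ddof=1)
    beyond = np.abs(z) > 3
    assert beyond.sum() == 1
    assert ids.size == 1 and beyond[ids[0]].any()


def test_plant_multivariate_outlier_exceeds_cutoff_in_7dim():
    rng = np.random.default_rng(1)
    # Correlated 7-dim scores so a within-3-SD pattern can break the correlation.
    L = rng.normal(size=(7, 7)) * 0.3 + np.eye(7)
    X = rng.normal(size=(500, 7)) @ L.T
    m = RatingMatrix(X, analogue_items(7, -1e6, 1e6), np.arange(500))
    out, ids = plant_outliers(m, n_uni=0, n_multi=3, seed=4)
    mu = out.scores.mean(axis=0)
    prec = np.linalg.inv(np.cov(out.scores, rowvar=False))
    sd = out.scores.std(axis=0, ddof=1)
    for i in ids:
        dvec = out.scores[i] - mu
        d2 = dvec @ prec @ dvec
        assert d2 > mahalanobis_cutoff(7, 0.001)  # 24.32
        assert np.all(np.abs(dvec) / sd <= 3.0)


def test_ground_truth_json_roundtrip(tmp_path, small_cohort):
    _, _, _, truth = small_cohort
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = GroundTruth.from_json(path)
    np.testing.assert_allclose(back.loadings, truth.loadings)
    np.testing.assert_array_equal(back.labels_w1, truth.labels_w1)
    np.testing.assert_array_equal(back.labels_w2, truth.labels_w2)
    np.testing.assert_allclose(back.latent_scores_w2, truth.latent_scores_w2)


def test_ordinal_thresholds_equiprobable():
    t = ordinal_thresholds(4)
    assert t.shape == (3,)
    assert np.all(np.diff(t) > 0)
    from scipy.stats import norm

    np.testing.assert_allclose(norm.cdf(t), [0.25, 0.5, 0.75], atol=1e-12)


def test_income_covariate_shift():
    cfg = CohortConfig(n_subjects=2000, seed=13, covariate_income_shift=-0.5)
    wave1, _, truth = generate_cohort(cfg)
    income = wave1.covariates["income"].to_numpy()
    normative = truth.labels_w2 == 0
    assert income[~normative].mean() < income[normative].mean()


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_subjects=0)
    with pytest.raises(ValueError):
        CohortConfig(transition_matrix=np.full((7, 6), 0.5))  # rows not stochastic
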