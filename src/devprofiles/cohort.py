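"""Synthetic two-wave questionnaire cohort generator.

Emulates the statistical structure the downstream analysis assumes in a
longitudinal behavioural-problems cohort: ~40 items loading on 6 orthogonal
latent factors, subjects drawn from planted cluster prototypes at each wave, a
planted row-stochastic childhood->adolescence transition matrix, MCAR item
missingness, and planted univariate/multivariate outliers.  Wave 1 is written
on continuous visual-analogue scales (0-100 mm); wave 2 is discretised to a
4-point ordinal scale at fixed latent thresholds.

Randomness: every operation draws from its own PCG64 stream seeded as
``SeedSequence([seed, STREAM_CODE])``, so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .ratings import RatingMatrix, analogue_items, ordinal_items

# Stream codes for the per-operation RNG splitting rule.
_STREAM_LATENT = 1
_STREAM_ITEMS_W1 = 2
_STREAM_ITEMS_W2 = 3
_STREAM_MISSING = 4
_STREAM_OUTLIERS = 5
_STREAM_COVARIATES = 6


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), stream])))


# Default planted prototypes (clusters x factors, SD units).  The six factors
# are read as anxiety, inattention, conduct, emotion, hyperactivity, motor;
# wave 1 has seven profiles (a large no-problem group plus single- and
# multi-domain problem groups), wave 2 has six.  Minimum pairwise Euclidean
# separation is ~1.6 SD.
DEFAULT_PROTOTYPES_W1 = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # no problems
        [2.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # anxiety
        [0.0, 2.0, 0.0, 0.0, 0.0, 0.0],   # inattention
        [0.0, 0.0, 2.0, 0.0, 0.0, 0.0],   # conduct
        [0.0, 0.0, 0.0, 2.0, 0.0, 0.0],   # emotion
        [1.5, 0.0, 0.0, 0.0, 1.5, 0.0],   # anxiety + hyperactivity
        [0.0, 0.0, 0.0, 1.5, 1.5, 1.5],   # motor + hyperactivity + emotion
    ]
)
DEFAULT_PROTOTYPES_W2 = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # no problems
        [0.0, 2.0, 0.0, 0.0, 0.0, 0.0],   # inattention
        [1.5, 0.0, 0.0, 0.0, 0.0, 1.5],   # anxiety + motor
        [0.0, 0.0, 0.0, 2.0, 0.0, 0.0],   # emotion
        [1.5, 1.5, 0.0, 1.5, 0.0, 0.0],   # anxiety + emotion + inattention
        [0.0, 0.0, 0.0, 0.0, 2.0, 0.0],   # hyperactivity
    ]
)
DEFAULT_WEIGHTS_W1 = np.array([0.50, 0.10, 0.06, 0.06, 0.10, 0.08, 0.10])
# Rows: wave-1 profiles above; columns: wave-2 profiles above.  Every profile
# sends a large share to the no-problem group, plus profile-specific
# enrichments (e.g. conduct problems -> mixed anxiety/emotion/inattention).
DEFAULT_TRANSITIONS = np.array(
    [
        [0.60, 0.05, 0.08, 0.15, 0.05, 0.07],
        [0.40, 0.05, 0.10, 0.30, 0.10, 0.05],
        [0.35, 0.15, 0.05, 0.25, 0.15, 0.05],
        [0.35, 0.05, 0.10, 0.10, 0.35, 0.05],
        [0.40, 0.05, 0.10, 0.30, 0.10, 0.05],
        [0.35, 0.10, 0.15, 0.15, 0.10, 0.15],
        [0.30, 0.35, 0.10, 0.10, 0.10, 0.05],
    ]
)


def _default(value, fallback):
    return fallback if value is None else np.asarray(value, dtype=float)


@dataclass
class CohortConfig:
    """Generating conditions for a two-wave cohort."""

    n_subjects: int = 3000
    n_items: int = 40
    n_factors: int = 6
    loading_strength: float = 0.7
    cluster_prototypes_w1: np.ndarray | None = None
    cluster_prototypes_w2: np.ndarray | None = None
    cluster_weights_w1: np.ndarray | None = None
    transition_matrix: np.ndarray | None = None
    noise_sd: float = 0.5
    missing_rate: float = 0.02
    n_uni_outliers: int = 10
    n_multi_outliers: int = 10
    analogue_range: tuple[float, float] = (0.0, 100.0)
    ordinal_levels_w2: int = 4
    covariate_income_shift: float = -0.2  # SD shift for transitioners into w2 cluster 3 (emotion)
    seed: int = 0

    def __post_init__(self):
        self.cluster_prototypes_w1 = _default(self.cluster_prototypes_w1, DEFAULT_PROTOTYPES_W1)
        self.cluster_prototypes_w2 = _default(self.cluster_prototypes_w2, DEFAULT_PROTOTYPES_W2)
        self.cluster_weights_w1 = _default(self.cluster_weights_w1, DEFAULT_WEIGHTS_W1)
        self.transition_matrix = _default(self.transition_matrix, DEFAULT_TRANSITIONS)
        k1, f1 = self.cluster_prototypes_w1.shape
        k2, f2 = self.cluster_prototypes_w2.shape
        if f1 != self.n_factors or f2 != self.n_factors:
            raise ValueError("prototype factor count does not match n_factors")
        if self.cluster_weights_w1.shape != (k1,):
            raise ValueError("cluster_weights_w1 shape mismatch")
        if self.transition_matrix.shape != (k1, k2):
            raise ValueError("transition_matrix shape mismatch")
        if abs(self.cluster_weights_w1.sum() - 1.0) > 1e-12:
            raise ValueError("cluster_weights_w1 must sum to 1")
        if np.max(np.abs(self.transition_matrix.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition_matrix rows must sum to 1")
        if self.n_subjects < 1 or self.n_items < 1:
            raise ValueError("n_subjects and n_items must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.loading_strength <= 1.0:
            raise ValueError("loading_strength must be in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def loadings(self) -> np.ndarray:
        """Items x factors loading matrix: items assigned round-robin to factors."""
        lam = np.zeros((self.n_items, self.n_factors))
        for j in range(self.n_items):
            lam[j, j % self.n_factors] = self.loading_strength
        return lam

    def uniquenesses(self) -> np.ndarray:
        lam = self.loadings()
        return 1.0 - np.sum(lam**2, axis=1)


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort, for recovery tests."""

    loadings: np.ndarray
    labels_w1: np.ndarray
    labels_w2: np.ndarray
    latent_scores_w1: np.ndarray
    latent_scores_w2: np.ndarray
    outlier_ids_w1: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    outlier_ids_w2: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_json(self, path) -> None:
        payload = {
            "loadings": self.loadings.tolist(),
            "labels_w1": self.labels_w1.tolist(),
            "labels_w2": self.labels_w2.tolist(),
            "latent_scores_w1": self.latent_scores_w1.tolist(),
            "latent_scores_w2": self.latent_scores_w2.tolist(),
            "outlier_ids_w1": self.outlier_ids_w1.tolist(),
            "outlier_ids_w2": self.outlier_ids_w2.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["loadings"], dtype=float),
            np.asarray(d["labels_w1"], dtype=int),
            np.asarray(d["labels_w2"], dtype=int),
            np.asarray(d["latent_scores_w1"], dtype=float),
            np.asarray(d["latent_scores_w2"], dtype=float),
            np.asarray(d["outlier_ids_w1"], dtype=int),
            np.asarray(d["outlier_ids_w2"], dtype=int),
        )


def _continuous_items(latent: np.ndarray, lam: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standardised continuous item scores: loadings . scores + unique noise."""
    psi = 1.0 - np.sum(lam**2, axis=1)
    unique = rng.standard_normal((latent.shape[0], lam.shape[0])) * np.sqrt(psi)
    return latent @ lam.T + unique


def ordinal_thresholds(n_levels: int) -> np.ndarray:
    """Equiprobable standard-normal thresholds separating ``n_levels`` categories."""
    return norm.ppf(np.arange(1, n_levels) / n_levels)


def generate_cohort(config: CohortConfig) -> tuple[RatingMatrix, RatingMatrix, GroundTruth]:
    """Draw a complete two-wave cohort plus its planted ground truth.

    Subjects get a wave-1 cluster from ``cluster_weights_w1`` and a wave-2
    cluster from the matching transition-matrix row.  Latent factor scores are
    the cluster prototype plus isotropic Normal(0, noise_sd) deviates; item
    scores are the factor model applied to them.  Wave-1 items are mapped
    affinely onto the analogue range and truncated; wave-2 items are cut at
    equiprobable Normal thresholds into ``ordinal_levels_w2`` categories.
    Missingness/outliers are planted afterwards by the dedicated operations.
    """
    cfg = config
    n = cfg.n_subjects
    lam = cfg.loadings()

    rng_lat = _rng(cfg.seed, _STREAM_LATENT)
    k1 = cfg.cluster_prototypes_w1.shape[0]
    labels_w1 = rng_lat.choice(k1, size=n, p=cfg.cluster_weights_w1)
    labels_w2 = np.empty(n, dtype=int)
    for c in range(k1):
        rows = labels_w1 == c
        labels_w2[rows] = rng_lat.choice(
            cfg.transition_matrix.shape[1], size=rows.sum(), p=cfg.transition_matrix[c]
        )
    latent_w1 = cfg.cluster_prototypes_w1[labels_w1] + cfg.noise_sd * rng_lat.standard_normal(
        (n, cfg.n_factors)
    )
    latent_w2 = cfg.cluster_prototypes_w2[labels_w2] + cfg.noise_sd * rng_lat.standard_normal(
        (n, cfg.n_factors)
    )

    cont_w1 = _continuous_items(latent_w1, lam, _rng(cfg.seed, _STREAM_ITEMS_W1))
    cont_w2 = _continuous_items(latent_w2, lam, _rng(cfg.seed, _STREAM_ITEMS_W2))

    lo, hi = cfg.analogue_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    # Affine map: 3 latent SD spans the half range; values beyond are truncated.
    mm_w1 = np.clip(mid + cont_w1 * (half / 3.0), lo, hi)

    cuts = ordinal_thresholds(cfg.ordinal_levels_w2)
    ord_w2 = 1.0 + np.searchsorted(cuts, cont_w2).astype(float).reshape(cont_w2.shape)

    subject_ids = np.arange(1, n + 1)
    cov = _covariates(cfg, labels_w2)
    wave1 = RatingMatrix(mm_w1, analogue_items(cfg.n_items, lo, hi), subject_ids, cov)
    wave2 = RatingMatrix(ord_w2, ordinal_items(cfg.n_items, cfg.ordinal_levels_w2), subject_ids.copy())
    truth = GroundTruth(lam, labels_w1, labels_w2, latent_w1, latent_w2)
    return wave1, wave2, truth


def _covariates(cfg: CohortConfig, labels_w2: np.ndarray):
    """Family covariates with a planted income deficit for emotion-profile transitioners."""
    import pandas as pd

    rng = _rng(cfg.seed, _STREAM_COVARIATES)
    n = cfg.n_subjects
    income = rng.normal(0.0, 1.0, n)
    income[labels_w2 == 3] += cfg.covariate_income_shift
    return pd.DataFrame(
        {
            "income": income,
            "siblings": rng.poisson(1.5, n).astype(float),
            "cognitive_score": rng.normal(0.0, 1.0, n),
        }
    )


def plant_missingness(matrix: RatingMatrix, rate: float, seed: int) -> RatingMatrix:
    """Mask each cell independently with probability ``rate`` (MCAR)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = matrix.copy()
    if rate > 0.0:
        rng = _rng(seed, _STREAM_MISSING)
        mask = rng.random(out.scores.shape) < rate
        out.scores[mask] = np.nan
    return out


def plant_outliers(
    matrix: RatingMatrix, n_uni: int, n_multi: int, seed: int
) -> tuple[RatingMatrix, np.ndarray]:
    """Inject univariate and multivariate outlying subjects.

    ``n_uni`` subjects get one item moved to the column mean + 5 column SD.
    ``n_multi`` subjects are moved along a direction that is cheap in
    per-coordinate z units but expensive in Mahalanobis distance (the
    smallest-eigenvalue direction of the sample covariance), scaled so the
    squared Mahalanobis distance clearly exceeds the chi-squared screening
    cut-off while every coordinate stays within 3 SD of its mean.
    """
    from scipy.stats import chi2

    n = matrix.n_subjects
    if n_uni + n_multi > n:
        raise ValueError("more planted outliers than subjects")
    out = matrix.copy()
    ids = np.array([], dtype=int)
    if n_uni == 0 and n_multi == 0:
        return out, ids
    rng = _rng(seed, _STREAM_OUTLIERS)
    chosen = rng.choice(n, size=n_uni + n_multi, replace=False)
    uni_ids, multi_ids = chosen[:n_uni], chosen[n_uni:]
    X = out.scores
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    for i in uni_ids:
        j = int(rng.integers(X.shape[1]))
        X[i, j] = mean[j] + 5.0 * sd[j]
    if n_multi:
        p = X.shape[1]
        cov = np.cov(X[~np.isnan(X).any(axis=1)], rowvar=False)
        w, V = np.linalg.eigh(cov)
        cutoff = chi2.ppf(1 - 0.001, df=p)
        prec = np.linalg.pinv(cov)
        # Candidate patterns, each capped at 2.9 SD per coordinate: the
        # smallest-variance eigenvector (cheap in z, expensive in Mahalanobis
        # for correlated items) and an all-coordinate pattern with its signs.
        u = V[:, 0]
        cands = [u / np.max(np.abs(u) / sd) * 2.9, np.where(u >= 0, 1.0, -1.0) * 2.9 * sd]
        d2 = [float(c @ prec @ c) for c in cands]
        shift = cands[int(np.argmax(d2))]
        if max(d2) <= cutoff:
            raise ValueError("cannot plant a multivariate outlier within 3 SD per coordinate")
        for i in multi_ids:
            X[i, :] = mean + shift
    ids = np.sort(chosen)
    return out, ids
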