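"""Cleaning chain for questionnaire ratings.

The pipeline order mirrors the source workflow: screen subjects with too many
missing items, impute the remainder with a multivariate-normal EM algorithm
(which preserves means, variances and covariances), remove univariate (|z| > 3)
and multivariate (squared Mahalanobis distance above the chi-squared 1-alpha
quantile) outliers, and discretise continuous visual-analogue items to ordinal
levels with kernel density estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, gaussian_kde

from .ratings import ItemScale, RatingMatrix


@dataclass
class ScreeningReport:
    """Which subjects survived each exclusion step, and the thresholds used.

    The four id sets partition the input ids.
    """

    kept_ids: np.ndarray
    excluded_missing_ids: np.ndarray
    excluded_univariate_ids: np.ndarray
    excluded_multivariate_ids: np.ndarray
    max_missing: int | None = None
    z_thresh: float | None = None
    mahalanobis_cutoff: float | None = None
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_kept": int(len(self.kept_ids)),
            "n_excluded_missing": int(len(self.excluded_missing_ids)),
            "n_excluded_univariate": int(len(self.excluded_univariate_ids)),
            "n_excluded_multivariate": int(len(self.excluded_multivariate_ids)),
            "max_missing": self.max_missing,
            "z_thresh": self.z_thresh,
            "mahalanobis_cutoff": self.mahalanobis_cutoff,
            "flags": self.flags,
        }


def screen_missing(matrix: RatingMatrix, max_missing: int = 5) -> tuple[RatingMatrix, ScreeningReport]:
    """Exclude subjects with strictly more than ``max_missing`` missing items."""
    n_missing = matrix.missing_mask.sum(axis=1)
    keep = n_missing <= max_missing
    report = ScreeningReport(
        kept_ids=matrix.subject_ids[keep],
        excluded_missing_ids=matrix.subject_ids[~keep],
        excluded_univariate_ids=np.array([], dtype=matrix.subject_ids.dtype),
        excluded_multivariate_ids=np.array([], dtype=matrix.subject_ids.dtype),
        max_missing=max_missing,
    )
    return matrix.subset(np.nonzero(keep)[0]), report


def em_impute(
    matrix: RatingMatrix, tol: float = 1e-6, max_iter: int = 200
) -> tuple[RatingMatrix, np.ndarray, np.ndarray, int]:
    """Fill missing cells with multivariate-normal EM conditional means.

    E-step: conditional expectations (and conditional covariances, which enter
    the expected scatter) of missing cells given the observed cells of the same
    subject.  M-step: update the mean vector and covariance matrix.  Converges
    when the largest absolute change in any parameter is below ``tol``.
    Imputed ordinal cells are rounded to the nearest valid level afterwards.

    Returns (completed matrix, mean, covariance, n_iterations).
    """
    X = matrix.scores.copy()
    mask = np.isnan(X)
    n, p = X.shape
    if (~mask).sum(axis=0).min() < 2:
        raise ValueError("every item needs at least 2 observed values")

    mu = np.nanmean(X, axis=0)
    Xc = np.where(mask, mu, X)
    sigma = np.cov(Xc, rowvar=False, ddof=0)
    sigma += np.eye(p) * 1e-10

    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    n_iter = 0
    converged = False
    ridge_flag = False
    for n_iter in range(1, max_iter + 1):
        filled = X.copy()
        extra = np.zeros((p, p))  # sum of conditional covariances over subjects
        for pi, pat in enumerate(patterns):
            rows = np.nonzero(inverse == pi)[0]
            m = np.nonzero(pat)[0]
            if m.size == 0:
                continue
            o = np.nonzero(~pat)[0]
            if o.size == 0:
                filled[np.ix_(rows, m)] = mu[m]
                extra[np.ix_(m, m)] += len(rows) * sigma[np.ix_(m, m)]
                continue
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            try:
                sol = np.linalg.solve(Soo, Smo.T)
            except np.linalg.LinAlgError:
                ridge_flag = True
                Soo = Soo + np.eye(o.size) * (1e-8 * np.trace(Soo) / o.size)
                sol = np.linalg.solve(Soo, Smo.T)
            resid = X[np.ix_(rows, o)] - mu[o]
            filled[np.ix_(rows, m)] = mu[m] + resid @ sol
            cond_cov = sigma[np.ix_(m, m)] - Smo @ sol
            extra[np.ix_(m, m)] += len(rows) * cond_cov
        mu_new = filled.mean(axis=0)
        centred = filled - mu_new
        sigma_new = (centred.T @ centred + extra) / n
        delta = max(np.max(np.abs(mu_new - mu)), np.max(np.abs(sigma_new - sigma)))
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break

    completed = matrix.copy()
    completed.scores = filled
    for j, meta in enumerate(matrix.item_meta):
        col = completed.scores[:, j]
        if meta.kind == "ordinal":
            completed.scores[:, j] = np.clip(np.round(col), 1, meta.levels)
        else:
            completed.scores[:, j] = np.clip(col, meta.low, meta.high)
    if not converged:
        completed_flags = {"em_converged": False}
    else:
        completed_flags = {"em_converged": True}
    if ridge_flag:
        completed_flags["em_ridge_stabilised"] = True
    completed.flags = completed_flags  # type: ignore[attr-defined]
    return completed, mu, sigma, n_iter


def mahalanobis_cutoff(n_dims: int, alpha: float = 0.001) -> float:
    """Upper-``alpha`` chi-squared quantile used to screen squared Mahalanobis distances."""
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(chi2.ppf(1.0 - alpha, df=n_dims))


def remove_outliers(
    scores: np.ndarray,
    subject_ids: np.ndarray | None = None,
    z_thresh: float = 3.0,
    alpha: float = 0.001,
) -> tuple[np.ndarray, ScreeningReport]:
    """Flag univariate (|z| > z_thresh) and multivariate (Mahalanobis) outliers.

    Both passes use the moments of the full pre-removal sample; a subject
    flagged by the univariate rule is not re-tested by the multivariate rule.
    Returns (kept boolean mask, report).
    """
    X = np.asarray(scores, dtype=float)
    n, p = X.shape
    if subject_ids is None:
        subject_ids = np.arange(n)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = (X - mean) / sd
    uni = np.any(np.abs(z) > z_thresh, axis=1)

    cov = np.cov(X, rowvar=False, ddof=1)
    flags = {}
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(cov)
        flags["singular_covariance"] = True
    centred = X - mean
    d2 = np.einsum("ij,jk,ik->i", centred, prec, centred)
    cutoff = mahalanobis_cutoff(p, alpha)
    multi = (d2 > cutoff) & ~uni
    keep = ~(uni | multi)
    report = ScreeningReport(
        kept_ids=np.asarray(subject_ids)[keep],
        excluded_missing_ids=np.array([], dtype=np.asarray(subject_ids).dtype),
        excluded_univariate_ids=np.asarray(subject_ids)[uni],
        excluded_multivariate_ids=np.asarray(subject_ids)[multi],
        z_thresh=z_thresh,
        mahalanobis_cutoff=cutoff,
        flags=flags,
    )
    return keep, report


def kde_discretise(
    values: np.ndarray, n_levels: int, bandwidth_rule: str = "silverman",
    grid_size: int = 512, value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Discretise continuous scores into ordinal levels at density minima.

    A Gaussian KDE is fitted to the observed values and evaluated on a
    ``grid_size``-point grid over the scale range; the ``n_levels - 1``
    deepest interior local minima of the density become cutpoints (ranked by
    density value, lowest first).  If fewer minima exist, the remaining
    cutpoints fall back to equal-probability quantiles.  Levels are assigned
    as 1 + number of cutpoints strictly below the value, so the mapping is
    monotone in the raw score.

    Returns (levels, cutpoints, degenerate_flag).
    """
    values = np.asarray(values, dtype=float)
    obs = values[~np.isnan(values)]
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if np.unique(obs).size < max(2, n_levels):
        # Degenerate input: cannot support n_levels categories.
        levels = np.ones_like(values)
        levels[np.isnan(values)] = np.nan
        return levels, np.array([]), True
    lo, hi = value_range if value_range is not None else (obs.min(), obs.max())
    kde = gaussian_kde(obs, bw_method=bandwidth_rule)
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_min = (dens[interior] < dens[interior - 1]) & (dens[interior] <= dens[interior + 1])
    minima = interior[is_min]
    order = np.argsort(dens[minima], kind="stable")  # deepest (lowest density) first
    chosen = list(grid[minima[order][: n_levels - 1]])
    if len(chosen) < n_levels - 1:
        # Equal-probability fallback for the remaining cutpoints.
        need = n_levels - 1 - len(chosen)
        qs = np.quantile(obs, np.arange(1, n_levels) / n_levels)
        for q in qs:
            if need == 0:
                break
            if not any(abs(q - c) < 1e-12 for c in chosen):
                chosen.append(float(q))
                need -= 1
    cutpoints = np.sort(np.asarray(chosen[: n_levels - 1]))
    levels = 1.0 + np.searchsorted(cutpoints, values, side="left")
    levels = levels.astype(float)
    levels[np.isnan(values)] = np.nan
    return levels, cutpoints, False


def discretise_wave(matrix: RatingMatrix, n_levels: int = 4,
                    bandwidth_rule: str = "silverman") -> RatingMatrix:
    """Apply :func:`kde_discretise` to every analogue item of a wave."""
    out = matrix.copy()
    meta = []
    for j, m in enumerate(matrix.item_meta):
        if m.kind == "analogue":
            lv, _, _ = kde_discretise(
                matrix.scores[:, j], n_levels, bandwidth_rule, value_range=(m.low, m.high)
            )
            out.scores[:, j] = lv
            meta.append(ItemScale("ordinal", levels=n_levels))
        else:
            meta.append(m)
    out.item_meta = meta
    return out
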