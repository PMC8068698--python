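"""Two-step maximum-likelihood polychoric correlations.

Thresholds come from inverse-Normal cumulative marginal proportions; the
correlation of the assumed latent bivariate Normal is then found by maximising
the multinomial likelihood of the observed contingency table over rho alone
(bounded scalar optimisation).  Rectangle probabilities use the vectorised
Genz algorithm in :mod:`devprofiles._bvn`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from ._bvn import bvn_cdf

RHO_MAX = 0.999
_INF = 8.5  # effective infinity for standard-normal thresholds


@dataclass
class PolychoricResult:
    rho: float
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    log_likelihood: float
    converged: bool
    clamped: bool = False


def _thresholds(codes: np.ndarray, n_cats: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_cats).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return norm.ppf(cum)


def _table_loglik(table: np.ndarray, tx: np.ndarray, ty: np.ndarray, rho: float) -> float:
    gx = np.concatenate([[-_INF], np.clip(tx, -_INF, _INF), [_INF]])
    gy = np.concatenate([[-_INF], np.clip(ty, -_INF, _INF), [_INF]])
    F = bvn_cdf(gx[:, None], gy[None, :], rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    P = np.clip(P, 1e-300, None)
    return float(np.sum(table * np.log(P)))


def polychoric_corr(x: np.ndarray, y: np.ndarray) -> PolychoricResult:
    """Polychoric correlation of two ordinal variables (two-step ML)."""
    x = np.asarray(x)
    y = np.asarray(y)
    ok = ~(np.isnan(x.astype(float)) | np.isnan(y.astype(float)))
    x, y = x[ok], y[ok]
    ux, cx = np.unique(x, return_inverse=True)
    uy, cy = np.unique(y, return_inverse=True)
    if ux.size < 2 or uy.size < 2:
        raise ValueError("each variable needs at least 2 observed categories")
    table = np.zeros((ux.size, uy.size))
    np.add.at(table, (cx, cy), 1.0)
    tx = _thresholds(cx, ux.size)
    ty = _thresholds(cy, uy.size)
    # Canonical argument order so rho(x, y) is bitwise identical to rho(y, x).
    swapped = (uy.size, tuple(ty)) < (ux.size, tuple(tx))
    if swapped:
        table = table.T.copy()
        tx, ty = ty, tx

    res = minimize_scalar(
        lambda r: -_table_loglik(table, tx, ty, r),
        bounds=(-RHO_MAX, RHO_MAX),
        method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    clamped = abs(rho) >= RHO_MAX - 1e-4
    if clamped:
        rho = float(np.sign(rho) * RHO_MAX)
    if swapped:
        tx, ty = ty, tx
    return PolychoricResult(
        rho=rho,
        thresholds_x=tx,
        thresholds_y=ty,
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
        clamped=clamped,
    )


def polychoric_matrix(scores: np.ndarray, return_flags: bool = False):
    """Pairwise polychoric correlation matrix of an ordinal rating matrix.

    If the pairwise matrix is not positive semi-definite it is repaired by
    clipping eigenvalues at 1e-6 and rescaling to unit diagonal.
    """
    X = np.asarray(scores, dtype=float)
    p = X.shape[1]
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            try:
                R[i, j] = R[j, i] = polychoric_corr(X[:, i], X[:, j]).rho
            except ValueError as exc:
                raise ValueError(f"polychoric failure for item pair ({i}, {j}): {exc}") from exc
    w, V = np.linalg.eigh(R)
    repaired = False
    if w.min() < 0:
        repaired = True
        w = np.clip(w, 1e-6, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    if return_flags:
        return R, {"psd_repaired": repaired}
    return R
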