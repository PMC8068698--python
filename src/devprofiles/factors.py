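"""Ordinal exploratory factor analysis on polychoric correlations.

Extraction is minimum-residual (minres): uniquenesses are chosen to minimise
the sum of squared off-diagonal residuals of ``R - Lambda Lambda'``, with the
loadings obtained from the leading eigenpairs of the reduced correlation
matrix.  Rotation is varimax.  Factor scores use the
regression (Thurstone) method and are re-standardised per factor.

Retention diagnostics: Horn-style parallel analysis against ordinal null data
discretised to each item's observed margins, and a bootstrap stability check
based on Tucker congruence with the full-sample solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .polychoric import polychoric_matrix


@dataclass
class FactorModel:
    loadings: np.ndarray              # items x factors, rotated
    uniquenesses: np.ndarray          # per item, in [0, 1]
    proportion_variance: np.ndarray   # per rotated factor
    rotation_matrix: np.ndarray
    extraction: str = "minres"
    rotation: str = "varimax"
    heywood: bool = False
    objective_path: list = field(default_factory=list)

    @property
    def total_variance(self) -> float:
        return float(self.proportion_variance.sum())

    @property
    def communalities(self) -> np.ndarray:
        return np.sum(self.loadings**2, axis=1)


@dataclass
class FactorScores:
    scores: np.ndarray  # subjects x factors, standardised
    method: str = "regression"


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax criterion: sum over factors of the variance of squared loadings."""
    L2 = np.asarray(loadings) ** 2
    return float(np.sum(L2.var(axis=0)))


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 1000,
            normalize: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by the SVD iteration.

    ``normalize`` applies Kaiser row normalisation before rotating.  The raw
    criterion is the default: it is what the SVD iteration maximises robustly
    (Kaiser weights can create exact saddle points on symmetric loading
    patterns, where the iteration cannot leave the start).

    Returns (rotated loadings, orthogonal rotation matrix).
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    if normalize:
        h = np.sqrt(np.sum(L**2, axis=1))
        h = np.where(h == 0, 1.0, h)
        L = L / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        tmp = Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p
        U, s, Vt = np.linalg.svd(L.T @ tmp)
        R = U @ Vt
        d_new = float(np.sum(s))
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    out = L @ R
    if normalize:
        out = out * h[:, None]
    return out, R


def _reduced_loadings(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    Rr = R - np.diag(psi)
    w, V = np.linalg.eigh(Rr)
    idx = np.argsort(w)[::-1][:k]
    w_k = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(w_k)


def _minres_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    lam = _reduced_loadings(R, psi, k)
    resid = R - lam @ lam.T
    off = resid - np.diag(np.diag(resid))
    return float(np.sum(off**2) / 2.0)


def efa(corr: np.ndarray, n_factors: int, n_obs: int | None = None) -> FactorModel:
    """Minres extraction + varimax rotation on a correlation matrix."""
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n_factors >= p:
        raise ValueError("n_factors must be smaller than the number of items")
    # SMC start values for the communalities.
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.005, 1.0)
    path: list[float] = [_minres_objective(psi0, R, n_factors)]
    res = minimize(
        _minres_objective,
        psi0,
        args=(R, n_factors),
        method="L-BFGS-B",
        bounds=[(0.001, 1.0)] * p,
        callback=lambda xk: path.append(_minres_objective(xk, R, n_factors)),
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    psi = np.asarray(res.x)
    heywood = bool(np.any(psi <= 0.0011))
    lam = _reduced_loadings(R, psi, n_factors)
    rotated, rot = varimax(lam)
    # Order factors by explained variance, largest first, and fix signs so the
    # largest-magnitude loading of each factor is positive.
    ssq = np.sum(rotated**2, axis=0)
    order = np.argsort(ssq)[::-1]
    rotated = rotated[:, order]
    rot = rot[:, order]
    signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(n_factors)])
    signs = np.where(signs == 0, 1.0, signs)
    rotated = rotated * signs
    rot = rot * signs
    comm = np.sum(rotated**2, axis=1)
    return FactorModel(
        loadings=rotated,
        uniquenesses=1.0 - comm,
        proportion_variance=np.sum(rotated**2, axis=0) / p,
        rotation_matrix=rot,
        heywood=heywood,
        objective_path=path,
    )


def factor_scores(scores: np.ndarray, corr: np.ndarray, model: FactorModel) -> FactorScores:
    """Regression (Thurstone) factor scores, re-standardised per factor."""
    X = np.asarray(scores, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    R = np.asarray(corr, dtype=float)
    try:
        W = np.linalg.solve(R, model.loadings)
    except np.linalg.LinAlgError:
        W = np.linalg.solve(R + np.eye(R.shape[0]) * 1e-8, model.loadings)
    F = Z @ W
    F = (F - F.mean(axis=0)) / F.std(axis=0, ddof=0)
    return FactorScores(scores=F)


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient (cosine) between two loading vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def _match_factors(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Greedy best-match of ``other``'s factors to ``ref`` by |congruence|."""
    k = ref.shape[1]
    congr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            congr[i, j] = tucker_congruence(ref[:, i], other[:, j])
    matched = np.zeros(k)
    used_r, used_o = set(), set()
    flat = sorted(
        ((abs(congr[i, j]), i, j) for i in range(k) for j in range(k)), reverse=True
    )
    for c, i, j in flat:
        if i in used_r or j in used_o:
            continue
        matched[i] = c
        used_r.add(i)
        used_o.add(j)
    return matched


def parallel_analysis(scores: np.ndarray, n_sim: int = 100, quantile: float = 0.95,
                      seed: int = 0) -> int:
    """Suggested factor count by parallel analysis on polychoric eigenvalues.

    Null datasets are independent Normal deviates discretised at each item's
    observed marginal category proportions, then run through the same
    polychoric pipeline.  The suggestion is the number of leading observed
    eigenvalues exceeding the ``quantile`` of their null counterparts.
    """
    X = np.asarray(scores, dtype=float)
    n, p = X.shape
    obs_eig = np.sort(np.linalg.eigvalsh(polychoric_matrix(X)))[::-1]
    # Per-item observed category proportions -> latent Normal thresholds.
    from scipy.stats import norm

    item_cuts = []
    item_values = []
    for j in range(p):
        vals, counts = np.unique(X[:, j], return_counts=True)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        item_cuts.append(norm.ppf(cum))
        item_values.append(vals)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 7])))
    sim_eigs = np.empty((n_sim, p))
    for s in range(n_sim):
        Z = rng.standard_normal((n, p))
        sim = np.empty_like(Z)
        for j in range(p):
            sim[:, j] = item_values[j][np.searchsorted(item_cuts[j], Z[:, j])]
        sim_eigs[s] = np.sort(np.linalg.eigvalsh(polychoric_matrix(sim)))[::-1]
    thresh = np.quantile(sim_eigs, quantile, axis=0)
    k = 0
    while k < p and obs_eig[k] > thresh[k]:
        k += 1
    return k


def bootstrap_stability(
    scores: np.ndarray,
    k_candidates,
    n_boot: int = 100,
    seed: int = 0,
    congruence_floor: float = 0.90,
) -> dict:
    """Bootstrap factor-stability check.

    For each candidate factor count, refit the polychoric EFA on ``n_boot``
    row resamples, align each solution to the full-sample solution by greedy
    absolute Tucker congruence, and call the count stable when every factor's
    95% percentile interval lower bound is at least ``congruence_floor``.
    Returns a dict with per-k results and ``best_k`` (largest stable count, or
    None).
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 8])))
    results = {}
    for k in k_candidates:
        full = efa(polychoric_matrix(X), k)
        congr = []
        dropped = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                boot = efa(polychoric_matrix(X[idx]), k)
            except ValueError:
                dropped += 1
                continue
            congr.append(_match_factors(full.loadings, boot.loadings))
        congr = np.asarray(congr)
        lower = np.percentile(congr, 2.5, axis=0)
        upper = np.percentile(congr, 97.5, axis=0)
        results[k] = {
            "stable": bool(np.all(lower >= congruence_floor)),
            "congruence_lower": lower,
            "congruence_upper": upper,
            "n_dropped": dropped,
            "high_drop_rate": dropped > 0.1 * n_boot,
        }
    stable_ks = [k for k, r in results.items() if r["stable"]]
    results["best_k"] = max(stable_ks) if stable_ks else None
    return results
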