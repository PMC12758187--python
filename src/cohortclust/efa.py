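"""Exploratory factor analysis of symptom questionnaire items.

Pipeline: suitability screening (KMO adequacy and Bartlett's sphericity
test), factor-count selection with Velicer's minimum average partial (MAP)
test, maximum-likelihood extraction on the Pearson correlation matrix,
oblique geomin rotation by gradient projection, a single loading-threshold
pruning pass with one re-extraction, and regression-method factor scores
(the posterior mode under a standard-normal factor prior for this
linear-Gaussian model).

Extraction follows the classical profile-likelihood formulation: the ML
discrepancy is minimised over the uniquenesses, with loadings recovered
from the eigenstructure of the uniqueness-scaled correlation matrix.
Geomin minimises  sum_i [ prod_j (lambda_ij^2 + eps) ]^(1/m)  with
eps = 0.01 over oblique rotations, via the gradient-projection algorithm
with multiple random starts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

log = logging.getLogger(__name__)

GEOMIN_EPS = 0.01
MIN_UNIQUENESS = 0.005


class HeywoodWarning(UserWarning):
    pass


@dataclass
class SuitabilityReport:
    kmo_overall: float
    kmo_per_item: pd.Series
    bartlett_statistic: float
    bartlett_df: int
    bartlett_p: float
    n_complete: int


@dataclass
class FactorModel:
    loadings: pd.DataFrame            # item x factor
    factor_correlations: np.ndarray   # factor x factor (Phi)
    uniquenesses: pd.Series
    retained_items: list
    dropped_items: list
    n_factors: int
    item_means: pd.Series
    item_sds: pd.Series
    rotation_criterion: float | None = None
    heywood_items: list = field(default_factory=list)
    scores: pd.DataFrame | None = None

    def fitted_correlation(self) -> np.ndarray:
        """Model-implied correlation  Lambda Phi Lambda' + Psi."""
        L = self.loadings.to_numpy()
        S = L @ self.factor_correlations @ L.T
        np.fill_diagonal(S, np.diag(S) + self.uniquenesses.to_numpy())
        return S


def _complete_rows(items: pd.DataFrame) -> pd.DataFrame:
    return items.dropna(axis=0, how="any")


def _correlation(items: pd.DataFrame) -> tuple[np.ndarray, int]:
    data = _complete_rows(items)
    n = len(data)
    if n < 3:
        raise ValueError("fewer than 3 complete rows")
    R = np.corrcoef(data.to_numpy(), rowvar=False)
    return R, n


def suitability(items: pd.DataFrame) -> SuitabilityReport:
    """KMO adequacy index and Bartlett's test of sphericity.

    KMO = sum(r^2) / (sum(r^2) + sum(q^2)) over off-diagonal pairs, where
    q are anti-image partial correlations. Bartlett's statistic is
    -[(n-1) - (2p+5)/6] * ln det(R) with df = p(p-1)/2.
    """
    p = items.shape[1]
    if p < 3:
        raise ValueError("need at least 3 items")
    R, n = _correlation(items)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet) or np.linalg.cond(R) > 1e12:
        bad = _collinear_items(items.columns, R)
        raise ValueError(f"singular correlation matrix; collinear items: {bad}")
    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = (R ** 2)[off]
    q2 = (Q ** 2)[off]
    denom = r2.sum() + q2.sum()
    kmo = r2.sum() / denom if denom > 0 else np.nan
    per_item = np.empty(p)
    for j in range(p):
        oj = np.ones(p, dtype=bool)
        oj[j] = False
        dj = (R[j, oj] ** 2).sum() + (Q[j, oj] ** 2).sum()
        per_item[j] = (R[j, oj] ** 2).sum() / dj if dj > 0 else np.nan

    chi2 = -((n - 1) - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = stats.chi2.sf(max(chi2, 0.0), df)
    return SuitabilityReport(
        kmo_overall=float(kmo),
        kmo_per_item=pd.Series(per_item, index=items.columns, name="kmo"),
        bartlett_statistic=float(chi2),
        bartlett_df=int(df),
        bartlett_p=float(pval),
        n_complete=n,
    )


def _collinear_items(columns, R) -> list:
    p = R.shape[0]
    pairs = []
    for i in range(p):
        for j in range(i + 1, p):
            if abs(R[i, j]) > 1 - 1e-8:
                pairs.append((columns[i], columns[j]))
    return pairs


def velicer_map(R: np.ndarray, revised: bool = False) -> int:
    """Velicer's minimum average partial test for the number of factors.

    For m = 0..p-2 the first m principal components are partialled out of
    R and the average squared (4th power if ``revised``) off-diagonal
    partial correlation is computed; the m minimising this criterion is
    returned.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if p < 3:
        raise ValueError("need at least 3 variables")
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    power = 4 if revised else 2
    off = ~np.eye(p, dtype=bool)

    crit = np.full(p - 1, np.inf)
    for m in range(p - 1):
        if m == 0:
            C = R
        else:
            A = vecs[:, :m] * np.sqrt(np.maximum(vals[:m], 0.0))
            C = R - A @ A.T
        d = np.diag(C).copy()
        if np.any(d < 1e-10):
            break
        P = C / np.sqrt(np.outer(d, d))
        crit[m] = np.mean(np.abs(P[off]) ** power)
    return int(np.argmin(crit))


# ---------------------------------------------------------------------------
# ML extraction
# ---------------------------------------------------------------------------

def _ml_discrepancy(uniq: np.ndarray, R: np.ndarray, m: int) -> float:
    scale = 1.0 / np.sqrt(uniq)
    Rs = R * np.outer(scale, scale)
    vals = np.linalg.eigvalsh(Rs)[::-1]
    tail = np.maximum(vals[m:], 1e-12)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _loadings_from_uniquenesses(uniq: np.ndarray, R: np.ndarray, m: int) -> np.ndarray:
    scale = 1.0 / np.sqrt(uniq)
    Rs = R * np.outer(scale, scale)
    vals, vecs = np.linalg.eigh(Rs)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    lam = np.sqrt(np.maximum(vals[:m] - 1.0, 0.0))
    return np.sqrt(uniq)[:, None] * vecs[:, :m] * lam[None, :]


def extract_ml(R: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """ML factor extraction on a correlation matrix.

    Returns the (unrotated) loading matrix and the uniqueness vector.
    Raises on non-convergence; uniquenesses pinned at the lower bound are
    the Heywood diagnostics surfaced by the caller.
    """
    p = R.shape[0]
    ledermann = (2 * p + 1 - np.sqrt(8 * p + 1)) / 2
    if m < 1 or m > ledermann:
        raise ValueError(f"m={m} outside [1, Ledermann bound {ledermann:.1f}]")
    # 1 - SMC starting values
    Rinv = np.linalg.inv(R)
    start = np.clip(1.0 / np.diag(Rinv), MIN_UNIQUENESS, 1.0)
    res = optimize.minimize(
        _ml_discrepancy, start, args=(R, m), method="L-BFGS-B",
        bounds=[(MIN_UNIQUENESS, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    if not res.success and res.status != 2:  # 2 = precision loss, still usable
        raise RuntimeError(f"ML factor extraction failed to converge: {res.message}")
    uniq = np.asarray(res.x)
    return _loadings_from_uniquenesses(uniq, R, m), uniq


# ---------------------------------------------------------------------------
# geomin rotation (oblique gradient projection)
# ---------------------------------------------------------------------------

def _geomin_value_grad(L: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    m = L.shape[1]
    L2 = L * L + eps
    pro = np.exp(np.log(L2).sum(axis=1) / m)
    f = float(pro.sum())
    G = (2.0 / m) * (L / L2) * pro[:, None]
    return f, G


def _gpf_oblique(A: np.ndarray, T0: np.ndarray, eps: float,
                 max_iter: int = 1000, tol: float = 1e-7):
    """Oblique gradient-projection rotation of the loading matrix A."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _geomin_value_grad(L, eps)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T @ np.diag((T * G).sum(axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        improved = False
        for _ in range(30):
            X = T - al * Gp
            X = X / np.sqrt((X * X).sum(axis=0))
            try:
                Ti2 = np.linalg.inv(X)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            L2m = A @ Ti2.T
            f2, Gq2 = _geomin_value_grad(L2m, eps)
            if f2 < f - 0.5 * s * s * al:
                T, Ti, L, f, Gq = X, Ti2, L2m, f2, Gq2
                G = -(L.T @ Gq @ Ti).T
                improved = True
                break
            al /= 2.0
        if not improved:
            converged = True  # no descent direction left at line-search floor
            break
    Phi = T.T @ T
    return L, Phi, f, converged


def geomin_rotate(A: np.ndarray, eps: float = GEOMIN_EPS, n_starts: int = 30,
                  seed: int = 0):
    """Best-of-n-starts oblique geomin rotation.

    Start 0 is the identity; the remainder are random oblique matrices with
    unit columns. Ties resolve to the lowest criterion, then lowest start
    index (achieved by strict improvement).
    """
    m = A.shape[1]
    if m == 1:
        return A.copy(), np.ones((1, 1)), _geomin_value_grad(A, eps)[0], True
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        if s == 0:
            T0 = np.eye(m)
        else:
            T0 = rng.standard_normal((m, m))
            T0 = T0 / np.sqrt((T0 * T0).sum(axis=0))
            if abs(np.linalg.det(T0)) < 1e-8:
                continue
        L, Phi, f, conv = _gpf_oblique(A, T0, eps)
        if best is None or f < best[2] - 1e-12:
            best = (L, Phi, f, conv)
    if best is None or not best[3]:
        raise RuntimeError("geomin rotation did not converge from any start")
    return best


def _orient_signs(L: np.ndarray, Phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip factor signs so each factor's largest-magnitude loading is positive."""
    L = L.copy()
    Phi = Phi.copy()
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] *= -1
            Phi[j, :] *= -1
            Phi[:, j] *= -1
    return L, Phi


# ---------------------------------------------------------------------------
# public fitting surface
# ---------------------------------------------------------------------------

def extract_and_rotate(items: pd.DataFrame, m: int, *, n_starts: int = 30,
                       seed: int = 0) -> FactorModel:
    """ML extraction of ``m`` factors followed by oblique geomin rotation."""
    data = _complete_rows(items)
    R, _ = _correlation(items)
    A, uniq = extract_ml(R, m)
    L, Phi, crit, _ = geomin_rotate(A, n_starts=n_starts, seed=seed)
    L, Phi = _orient_signs(L, Phi)
    heywood = [c for c, u in zip(items.columns, uniq) if u <= MIN_UNIQUENESS + 1e-9]
    if heywood:
        log.warning("Heywood cases (uniqueness at bound) for items: %s", heywood)
    cols = [f"factor_{j + 1}" for j in range(m)]
    return FactorModel(
        loadings=pd.DataFrame(L, index=items.columns, columns=cols),
        factor_correlations=Phi,
        uniquenesses=pd.Series(uniq, index=items.columns, name="uniqueness"),
        retained_items=list(items.columns),
        dropped_items=[],
        n_factors=m,
        item_means=data.mean(),
        item_sds=data.std(ddof=1),
        rotation_criterion=float(crit),
        heywood_items=heywood,
    )


def items_below_threshold(loadings: pd.DataFrame, threshold: float) -> list:
    """Items whose maximum absolute loading is strictly below the threshold."""
    keep = loadings.abs().max(axis=1) >= threshold
    return list(loadings.index[~keep])


def prune_and_refit(items: pd.DataFrame, m: int, threshold: float = 0.4, *,
                    n_starts: int = 30, seed: int = 0) -> FactorModel:
    """Single pruning pass: fit, drop items below the loading threshold, refit once.

    Cross-loading items are retained; only items with no absolute loading
    reaching the threshold are dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    model = extract_and_rotate(items, m, n_starts=n_starts, seed=seed)
    dropped = items_below_threshold(model.loadings, threshold)
    if not dropped:
        return model
    retained = [c for c in items.columns if c not in set(dropped)]
    if not retained:
        raise ValueError("pruning dropped every item")
    refit = extract_and_rotate(items[retained], m, n_starts=n_starts, seed=seed)
    refit.dropped_items = dropped
    for j in range(m):
        if not (refit.loadings.abs().iloc[:, j] >= threshold).any():
            log.warning("factor %d has no loading above %.2f after pruning", j + 1,
                        threshold)
    return refit


def factor_scores(model: FactorModel, items: pd.DataFrame, *,
                  min_item_fraction: float = 0.5) -> pd.DataFrame:
    """Regression-method factor scores (posterior mode under a N(0, Phi) prior).

    scores = z Sigma^{-1} Lambda Phi with Sigma the fitted correlation.
    Participants missing more than ``1 - min_item_fraction`` of the
    retained items get NaN scores.
    """
    cols = model.retained_items
    present = items.reindex(columns=cols)
    z = (present - model.item_means[cols]) / model.item_sds[cols]
    L = model.loadings.to_numpy()
    Phi = model.factor_correlations
    Sigma = model.fitted_correlation()
    out = np.full((len(items), model.n_factors), np.nan)
    zv = z.to_numpy()
    obs_mask = ~np.isnan(zv)
    frac = obs_mask.mean(axis=1)
    # group rows by missingness pattern so each pattern solves one system
    patterns = {}
    for i in range(len(items)):
        if frac[i] < min_item_fraction:
            continue
        patterns.setdefault(obs_mask[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        msk = np.frombuffer(key, dtype=bool)
        B = np.linalg.solve(Sigma[np.ix_(msk, msk)], L[msk] @ Phi)
        out[rows] = zv[np.ix_(rows, msk)] @ B
    return pd.DataFrame(out, index=items.index, columns=model.loadings.columns)


def fit_efa(items: pd.DataFrame, *, threshold: float = 0.4, m: int | None = None,
            n_starts: int = 30, seed: int = 0) -> FactorModel:
    """Full EFA stage: MAP factor count (unless given), prune-refit, scores."""
    if m is None:
        R, _ = _correlation(items)
        m = max(velicer_map(R), 1)
    model = prune_and_refit(items, m, threshold, n_starts=n_starts, seed=seed)
    model.scores = factor_scores(model, items)
    return model
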