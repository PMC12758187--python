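"""Latent profile analysis: Gaussian mixture EM with profile-shared
diagonal covariance, bootstrap likelihood-ratio selection of the profile
count, and maximum-posterior assignment.

The covariance structure is "equal variances, covariances fixed to zero":
one variance per indicator, shared by every profile, with all covariances
structurally zero. This is the most constrained of the standard LPA model
families and is fitted by a dedicated EM loop so the structure is exact
(library mixtures offer shared-full or per-component-diagonal, not
shared-diagonal).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

log = logging.getLogger(__name__)

VARIANCE_FLOOR_FACTOR = 1e-6


@dataclass
class LPAModel:
    k: int
    weights: np.ndarray            # (k,)
    means: np.ndarray              # (k, d)
    variances: np.ndarray          # (d,), shared across profiles
    log_likelihood: float
    posteriors: np.ndarray         # (n, k)
    labels: np.ndarray             # (n,)
    converged: bool
    n_iter: int
    ll_trace: np.ndarray = field(repr=False, default=None)

    def simulate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.choice(self.k, size=n, p=self.weights)
        return self.means[z] + rng.standard_normal((n, len(self.variances))) * np.sqrt(
            self.variances
        )


def _log_density(X, weights, means, variances):
    """(n, k) matrix of log w_k + log N(x | mu_k, diag(sigma2))."""
    n, d = X.shape
    const = -0.5 * (d * np.log(2 * np.pi) + np.log(variances).sum())
    diff = X[:, None, :] - means[None, :, :]
    quad = -0.5 * (diff ** 2 / variances[None, None, :]).sum(axis=2)
    return np.log(weights)[None, :] + const + quad


def _fit_once(X, k, rng, max_iter, tol, floor):
    n, d = X.shape
    centers, _ = kmeans_plusplus(X, n_clusters=k,
                                 random_state=int(rng.integers(2 ** 31)))
    means = centers.copy()
    weights = np.full(k, 1.0 / k)
    variances = X.var(axis=0).clip(min=floor)
    ll_prev = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logjoint = _log_density(X, weights, means, variances)
        lse = logsumexp(logjoint, axis=1)
        ll = float(lse.sum())
        # EM guarantees monotone log-likelihood; a decrease beyond rounding
        # indicates an implementation fault, so fail loudly.
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {it}: {ll_prev} -> {ll}"
            )
        trace.append(ll)
        resp = np.exp(logjoint - lse[:, None])
        Nk = resp.sum(axis=0)
        if np.any(Nk < 1e-8):
            # re-seed empty components from the point worst explained
            for j in np.flatnonzero(Nk < 1e-8):
                worst = int(np.argmin(lse))
                log.debug("reinitializing empty profile %d from point %d", j, worst)
                means[j] = X[worst]
                weights = np.full(k, 1.0 / k)
            ll_prev = -np.inf
            continue
        weights = Nk / n
        means = (resp.T @ X) / Nk[:, None]
        diff2 = (X[:, None, :] - means[None, :, :]) ** 2
        variances = ((resp[:, :, None] * diff2).sum(axis=(0, 1)) / n).clip(min=floor)
        if ll - ll_prev < tol * max(1.0, abs(ll)):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    logjoint = _log_density(X, weights, means, variances)
    lse = logsumexp(logjoint, axis=1)
    posteriors = np.exp(logjoint - lse[:, None])
    return weights, means, variances, float(lse.sum()), posteriors, converged, it, \
        np.asarray(trace)


def fit_lpa(scores, k: int, seed: int = 0, *, n_restarts: int = 10,
            max_iter: int = 1000, tol: float = 1e-8) -> LPAModel:
    """Fit a k-profile model by EM with multiple kmeans++ restarts.

    The best final likelihood wins; ties resolve to the earliest restart.
    k = 1 is fitted in closed form.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    floor = VARIANCE_FLOOR_FACTOR * float(X.var(axis=0).mean() + 1e-300)

    if k == 1:
        mu = X.mean(axis=0, keepdims=True)
        var = X.var(axis=0).clip(min=floor)
        ll = float(_log_density(X, np.ones(1), mu, var).sum())
        post = np.ones((n, 1))
        return LPAModel(1, np.ones(1), mu, var, ll, post, np.zeros(n, dtype=int),
                        True, 0, np.asarray([ll]))

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        fit = _fit_once(X, k, rng, max_iter, tol, floor)
        if best is None or fit[3] > best[3] + 1e-12:
            best = fit
    weights, means, variances, ll, post, conv, it, trace = best
    labels = post.argmax(axis=1)  # argmax breaks ties toward the lowest index
    return LPAModel(k, weights, means, variances, ll, post, labels, conv, it, trace)


def assign_profiles(model: LPAModel, ids=None) -> pd.DataFrame:
    """Hard assignment to the profile with the greatest membership probability.

    Exact posterior ties resolve to the lowest profile index and are logged.
    """
    post = model.posteriors
    labels = post.argmax(axis=1)
    maxp = post.max(axis=1)
    ties = (post == maxp[:, None]).sum(axis=1) > 1
    if ties.any():
        log.info("posterior ties broken toward the lowest profile index for %d "
                 "participants", int(ties.sum()))
    index = ids if ids is not None else pd.RangeIndex(len(labels))
    return pd.DataFrame({"profile": labels, "max_posterior": maxp}, index=index)


def blrt_select(scores, k_max: int, *, n_boot: int = 99, alpha: float = 0.05,
                seed: int = 0, n_restarts: int = 10, boot_restarts: int = 3,
                boot_max_iter: int = 250, boot_tol: float = 1e-7,
                max_failure_fraction: float = 0.2) -> tuple[int, pd.DataFrame]:
    """Sequential bootstrap likelihood-ratio selection of the profile count.

    For k = 2..k_max the observed statistic 2*(ll_k - ll_{k-1}) is compared
    with a parametric-bootstrap null (data simulated from the fitted k-1
    model, both models refitted); p = (1 + #{boot >= obs}) / (n_valid + 1).
    Testing stops at the first non-significant k; the returned count is the
    largest k whose test (and all before it) reached p < alpha.

    Returns (selected_k, table of per-k statistics and p-values).
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    selected = 1
    model_prev = fit_lpa(X, 1, seed=int(rng.integers(2 ** 31)),
                         n_restarts=n_restarts)
    for k in range(2, k_max + 1):
        model_k = fit_lpa(X, k, seed=int(rng.integers(2 ** 31)),
                          n_restarts=n_restarts)
        obs = max(2.0 * (model_k.log_likelihood - model_prev.log_likelihood), 0.0)
        boots, failures = [], 0
        for _ in range(n_boot):
            sim = model_prev.simulate(n, rng)
            try:
                b0 = fit_lpa(sim, k - 1, seed=int(rng.integers(2 ** 31)),
                             n_restarts=boot_restarts, max_iter=boot_max_iter,
                             tol=boot_tol)
                b1 = fit_lpa(sim, k, seed=int(rng.integers(2 ** 31)),
                             n_restarts=boot_restarts, max_iter=boot_max_iter,
                             tol=boot_tol)
            except (AssertionError, ValueError):
                failures += 1
                continue
            boots.append(max(2.0 * (b1.log_likelihood - b0.log_likelihood), 0.0))
        if failures > max_failure_fraction * n_boot:
            raise RuntimeError(
                f"{failures}/{n_boot} bootstrap refits failed at k={k}"
            )
        boots = np.asarray(boots)
        p = (1.0 + np.sum(boots >= obs)) / (len(boots) + 1.0)
        rows.append({"k": k, "statistic": obs, "p": p, "n_boot_valid": len(boots),
                     "n_boot_failed": failures})
        if p < alpha:
            selected = k
            model_prev = model_k
        else:
            break
    return selected, pd.DataFrame(rows)
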