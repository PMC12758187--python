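"""Neighborhood-based multi-omics clustering.

Each omic block yields a participant similarity graph: a scaled
exponential kernel on Euclidean distances (the SNF/NEMO convention),
converted to a k-nearest-neighbor *relative* similarity that is
row-normalized over each participant's neighborhood and then symmetrized.
Blocks are merged by averaging each pair's relative similarity over the
blocks in which both participants were measured — the mechanism that lets
participants with partial modality coverage stay in the analysis. The
cluster count comes from the eigengap of the symmetric normalized
Laplacian, and labels from spectral clustering.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

MU = 0.5  # kernel bandwidth multiplier


@dataclass
class SimilarityGraph:
    nodes: pd.Index
    W: np.ndarray       # full affinity (scaled exponential kernel)
    S: np.ndarray       # symmetrized kNN relative similarity
    k_nn: int


def default_k_nn(n: int) -> int:
    """Neighborhood size convention: round(n / 6), at least 1."""
    return max(1, int(round(n / 6)))


def block_affinity(block: pd.DataFrame, k_nn: int | None = None, *,
                   standardize: bool = True) -> SimilarityGraph:
    """Scaled-exponential-kernel affinity and kNN relative similarity.

    d_ij is the Euclidean distance after per-feature z-scoring;
    eps_ij = (mean kNN distance of i + mean kNN distance of j + d_ij) / 3;
    W_ij = exp(-d_ij^2 / (mu * eps_ij)) with mu = 0.5. The relative
    similarity row-normalizes W over NN(i) (self excluded) and is
    symmetrized as (S + S') / 2.
    """
    X = block.to_numpy(dtype=float)
    n = X.shape[0]
    if k_nn is None:
        k_nn = default_k_nn(n)
    if not 1 <= k_nn < n:
        raise ValueError(f"need n > k_nn >= 1 (n={n}, k_nn={k_nn})")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        constant = sd <= 0
        if constant.any():
            log.warning("dropping %d constant features", int(constant.sum()))
            X = X[:, ~constant]
            sd = sd[~constant]
        X = (X - X.mean(axis=0)) / sd

    D = cdist(X, X)
    # mean distance to the k_nn nearest neighbors, self excluded
    D_no_self = D.copy()
    np.fill_diagonal(D_no_self, np.inf)
    nn_idx = np.argsort(D_no_self, axis=1, kind="stable")[:, :k_nn]
    nn_dist = np.take_along_axis(D_no_self, nn_idx, axis=1)
    mean_nn = nn_dist.mean(axis=1)

    eps = (mean_nn[:, None] + mean_nn[None, :] + D) / 3.0
    eps = np.maximum(eps, 1e-300)
    W = np.exp(-(D ** 2) / (MU * eps))

    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), k_nn)
    cols = nn_idx.ravel()
    denom = W[rows, cols].reshape(n, k_nn).sum(axis=1)
    denom = np.maximum(denom, 1e-300)
    S[rows, cols] = W[rows, cols] / np.repeat(denom, k_nn)
    S = (S + S.T) / 2.0
    return SimilarityGraph(nodes=block.index, W=W, S=S, k_nn=k_nn)


def merge_blocks(graphs: dict, mask: pd.DataFrame | None = None
                 ) -> tuple[pd.DataFrame, list]:
    """Average relative similarities over blocks measuring both participants.

    Participants sharing no block with any other participant are removed
    (logged); pairs with no shared block among the retained participants
    get similarity 0.

    Returns (merged similarity DataFrame, excluded participant ids).
    """
    if not graphs:
        raise ValueError("need at least one block graph")
    all_ids = pd.Index([])
    for g in graphs.values():
        all_ids = all_ids.union(g.nodes)
    if mask is not None:
        all_ids = all_ids.intersection(mask.index)
    n = len(all_ids)
    pos = {pid: i for i, pid in enumerate(all_ids)}
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for name, g in graphs.items():
        idx = np.asarray([pos[pid] for pid in g.nodes if pid in pos])
        keep = [j for j, pid in enumerate(g.nodes) if pid in pos]
        sub = g.S[np.ix_(keep, keep)]
        total[np.ix_(idx, idx)] += sub
        count[np.ix_(idx, idx)] += 1.0

    shared = count.copy()
    np.fill_diagonal(shared, 0.0)
    isolated = shared.sum(axis=1) == 0
    excluded = list(all_ids[isolated])
    if excluded:
        log.warning("excluding %d participants sharing no block with any other: %s",
                    len(excluded), excluded)
    keep = ~isolated
    total, count = total[np.ix_(keep, keep)], count[np.ix_(keep, keep)]
    ids = all_ids[keep]
    merged = np.where(count > 0, total / np.maximum(count, 1.0), 0.0)
    merged = (merged + merged.T) / 2.0
    return pd.DataFrame(merged, index=ids, columns=ids), excluded


def _normalized_laplacian(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    d = S.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-300))
    L = np.eye(len(S)) - (S * d_inv_sqrt[:, None]) * d_inv_sqrt[None, :]
    return (L + L.T) / 2.0


def estimate_num_clusters(S, k_range: tuple[int, int] = (2, 15)) -> int:
    """Eigengap heuristic on the symmetric normalized Laplacian spectrum.

    Returns the k in ``k_range`` maximizing lambda_{k+1} - lambda_k
    (eigenvalues ascending). Near-zero eigenvalues beyond the first
    indicate a disconnected graph and are reported.
    """
    S = S.to_numpy() if isinstance(S, pd.DataFrame) else np.asarray(S)
    n = len(S)
    vals = np.linalg.eigvalsh(_normalized_laplacian(S))
    n_zero = int(np.sum(vals < 1e-10))
    if n_zero > 1:
        log.warning("similarity graph has ~%d connected components", n_zero)
    kmin, kmax = k_range
    kmax = min(kmax, n - 1)
    gaps = {k: vals[k] - vals[k - 1] for k in range(max(kmin, 2), kmax + 1)}
    return max(gaps, key=lambda k: (gaps[k], -k))


def spectral_cluster(S, k: int, seed: int = 0, *, n_init: int = 30) -> np.ndarray:
    """Spectral clustering: bottom-k Laplacian eigenvectors, row-normalized,
    k-means with seeded restarts."""
    S_arr = S.to_numpy() if isinstance(S, pd.DataFrame) else np.asarray(S)
    n = len(S_arr)
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n (k={k}, n={n})")
    vals, vecs = np.linalg.eigh(_normalized_laplacian(S_arr))
    U = vecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(U)


def nemo_pipeline(blocks: dict, mask: pd.DataFrame | None = None, *,
                  k: int | None = None, k_nn: int | None = None,
                  k_range: tuple[int, int] = (2, 15), seed: int = 0,
                  log_counts: bool = True) -> tuple[pd.Series, pd.DataFrame, int]:
    """Full biological clustering stage over named feature DataFrames.

    Count blocks should already be TSS-scaled and filtered; with
    ``log_counts`` they are log10(x + 1e-6) transformed before
    standardization (intensity blocks are log10'd too, guarded to
    positive values).
    """
    graphs = {}
    for name, df in blocks.items():
        X = df
        if log_counts:
            X = np.log10(df.clip(lower=0) + 1e-6)
        graphs[name] = block_affinity(X, k_nn=k_nn)
    merged, _ = merge_blocks(graphs, mask)
    if k is None:
        k = estimate_num_clusters(merged, k_range)
    labels = spectral_cluster(merged, k, seed=seed)
    return pd.Series(labels, index=merged.index, name="biological_cluster"), merged, k
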