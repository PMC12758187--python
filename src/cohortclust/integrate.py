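"""Merged consensus integration of symptom and biological clusterings.

The two stability analyses each produce a participant-pair consensus
matrix. Their unweighted average (restricted to participants present in
both) is treated as a similarity matrix: complete-linkage hierarchical
clustering runs on D = 1 - C, the cluster count is selected by scanning a
range of cuts and scoring each with the silhouette (computed from D
directly) and a medoid-form Davies-Bouldin index, and the stability of the
integrated clusters is assessed with the same location-test machinery used
upstream, reading consensus values from the merged matrix itself.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree as _cut_tree
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .stability import ConsensusResult, StabilityVerdict, stability_from_consensus

log = logging.getLogger(__name__)


@dataclass
class IntegrationResult:
    participant_ids: pd.Index
    C_int: np.ndarray
    linkage_tree: np.ndarray | None = None
    k_selected: int | None = None
    dbi_by_k: dict = field(default_factory=dict)
    silhouette_by_k: dict = field(default_factory=dict)
    dbi_agrees: bool | None = None
    labels: np.ndarray | None = None
    verdicts: list = field(default_factory=list)


def merge_consensus(res_sym: ConsensusResult, res_bio: ConsensusResult
                    ) -> IntegrationResult:
    """Unweighted element-wise average of two consensus matrices.

    Restricted to the participant intersection; where one matrix has an
    undefined entry (pair never co-sampled) the other is used alone.
    """
    ids = res_sym.participant_ids.intersection(res_bio.participant_ids)
    if len(ids) == 0:
        raise ValueError("no participants shared between the two consensus analyses")
    A = res_sym.consensus_frame().loc[ids, ids].to_numpy()
    B = res_bio.consensus_frame().loc[ids, ids].to_numpy()
    stacked = np.stack([A, B])
    with np.errstate(invalid="ignore"):
        C = np.nanmean(stacked, axis=0)
    single = np.isnan(A) ^ np.isnan(B)
    if single.any():
        log.info("%d pairs defined in only one modality; using it alone",
                 int(single.sum() // 2))
    return IntegrationResult(participant_ids=ids, C_int=C)


def _distance(C: np.ndarray) -> np.ndarray:
    D = 1.0 - np.asarray(C, dtype=float)
    D = np.clip(D, 0.0, 1.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def consensus_linkage(C: np.ndarray) -> np.ndarray:
    """Complete-linkage tree on D = 1 - C (standard 4-column merge format)."""
    return linkage(squareform(_distance(C), checks=False), method="complete")


def cut_consensus_tree(C: np.ndarray, k: int, tree: np.ndarray | None = None
                       ) -> np.ndarray:
    """Cut the complete-linkage tree of 1 - C into k clusters (labels 0-based).

    Cuts by merge order (undo the last k-1 merges), so exactly k clusters
    result even when merge heights tie — consensus-derived distances tie
    at 1.0 whenever some cross-cluster pair was never co-assigned.
    """
    n = len(C)
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n (k={k}, n={n})")
    if tree is None:
        tree = consensus_linkage(C)
    return _cut_tree(tree, n_clusters=k).ravel()


def medoid_dbi(D: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index in medoid form for pure-distance data.

    Cluster center = medoid (member minimizing summed within-cluster
    distance); scatter = mean distance to the medoid; separation =
    medoid-medoid distance.
    """
    labs = np.unique(labels)
    medoids, scatters = [], []
    for lab in labs:
        members = np.flatnonzero(labels == lab)
        sub = D[np.ix_(members, members)]
        med_local = int(np.argmin(sub.sum(axis=1)))
        medoid = members[med_local]
        medoids.append(medoid)
        scatters.append(sub[med_local].mean())
    k = len(labs)
    if k < 2:
        return np.nan
    ratios = np.zeros(k)
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            sep = D[medoids[i], medoids[j]]
            if sep <= 0:
                worst = np.inf
                break
            worst = max(worst, (scatters[i] + scatters[j]) / sep)
        ratios[i] = worst
    return float(ratios.mean())


def select_k(C: np.ndarray, k_range: tuple[int, int] = (2, 15), *,
             tree: np.ndarray | None = None
             ) -> tuple[int, dict, dict, bool]:
    """Scan tree cuts; silhouette (primary) and medoid DBI per k.

    Returns (k at maximum silhouette, dbi_by_k, silhouette_by_k,
    whether the DBI minimum agrees). Degenerate cuts (single cluster or
    all singletons) are skipped with a warning.
    """
    D = _distance(C)
    n = len(D)
    if tree is None:
        tree = consensus_linkage(C)
    kmin, kmax = k_range
    kmax = min(kmax, n - 1)
    sil, dbi = {}, {}
    for k in range(max(kmin, 2), kmax + 1):
        labels = cut_consensus_tree(C, k, tree)
        n_eff = len(np.unique(labels))
        if n_eff < 2 or n_eff >= n:
            log.warning("cut at k=%d degenerate (%d effective clusters); skipped",
                        k, n_eff)
            continue
        sil[k] = float(silhouette_score(D, labels, metric="precomputed"))
        dbi[k] = medoid_dbi(D, labels)
    if not sil:
        raise ValueError("no valid cut in the scanned range")
    k_sil = max(sil, key=lambda k: (sil[k], -k))
    k_dbi = min(dbi, key=lambda k: (dbi[k], k))
    agrees = k_sil == k_dbi
    if not agrees:
        log.warning("selection criteria disagree: silhouette argmax k=%d, "
                    "DBI argmin k=%d; silhouette is the primary selector",
                    k_sil, k_dbi)
    return k_sil, dbi, sil, agrees


def integrated_stability(C_int: np.ndarray, labels: np.ndarray, *,
                         threshold: float = 0.5, alpha: float = 0.05,
                         seed: int = 0) -> list[StabilityVerdict]:
    """Stability of the integrated clusters, read from the merged consensus."""
    return stability_from_consensus(C_int, labels, threshold=threshold,
                                    alpha=alpha, seed=seed)


def integrate(res_sym: ConsensusResult, res_bio: ConsensusResult, *,
              k_range: tuple[int, int] = (2, 15), k: int | None = None,
              seed: int = 0) -> IntegrationResult:
    """Full integration stage: merge, select k, cut, assess stability."""
    result = merge_consensus(res_sym, res_bio)
    tree = consensus_linkage(result.C_int)
    result.linkage_tree = tree
    if k is None:
        k, dbi, sil, agrees = select_k(result.C_int, k_range, tree=tree)
        result.dbi_by_k, result.silhouette_by_k, result.dbi_agrees = dbi, sil, agrees
    result.k_selected = k
    result.labels = cut_consensus_tree(result.C_int, k, tree)
    result.verdicts = integrated_stability(result.C_int, result.labels, seed=seed)
    return result
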