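"""Bootstrap pair-consensus cluster stability.

A reference clustering is computed once on the full participant set. The
clustering routine is then re-run on many subsamples (by default 1,000
draws of 75 % of participants without replacement). Two symmetric integer
matrices accumulate over iterations: M counts how often each pair of
participants was co-sampled, I how often a co-sampled pair landed in the
same cluster. The consensus matrix C = I / M (element-wise, where M > 0)
is 1 for pairs always clustered together and 0 for pairs never clustered
together.

A reference cluster is called stable when its within-cluster consensus
values exceed 0.5 by a one-sided one-sample location test: a t-test when
the values pass a Shapiro-Wilk normality check, a Wilcoxon signed-rank
test otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    participant_ids: pd.Index
    reference_labels: np.ndarray
    M: np.ndarray                  # pair co-sampling counts
    I: np.ndarray                  # pair co-assignment counts
    C: np.ndarray                  # I / M where M > 0, else NaN
    n_boot: int
    subsample_fraction: float
    n_failures: int = 0
    iterations: list = field(default_factory=list, repr=False)

    def consensus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.participant_ids,
                            columns=self.participant_ids)


@dataclass
class StabilityVerdict:
    cluster_id: int
    n_members: int
    n_pairs: int
    mean_consensus: float
    median_consensus: float
    normality_p: float | None
    test_used: str              # "t", "wilcoxon", "none"
    test_p: float | None
    stable: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def bootstrap_consensus(n_or_ids, cluster_fn, *, n_boot: int = 1000,
                        fraction: float = 0.75, seed: int = 0,
                        store_iterations: bool = False,
                        max_failure_fraction: float = 0.05) -> ConsensusResult:
    """Accumulate pair co-sampling (M) and co-assignment (I) counts.

    Parameters
    ----------
    n_or_ids
        Participant count or an index of participant ids.
    cluster_fn
        Callback mapping an integer-position array (a participant subset)
        to cluster labels of the same length. It is first called on the
        full range to obtain the reference clustering, which subsequent
        iterations never alter. Labels are only compared within one call,
        so any labeling convention works.
    seed
        Seeds a dedicated subsampling stream; the callback's own
        randomness cannot desynchronize the subsample sequence.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if isinstance(n_or_ids, (int, np.integer)):
        ids = pd.RangeIndex(int(n_or_ids))
    else:
        ids = pd.Index(n_or_ids)
    n = len(ids)
    m = int(np.floor(fraction * n))
    if m < 2:
        raise ValueError("subsample too small to contain pairs")

    reference = np.asarray(cluster_fn(np.arange(n)))
    if len(reference) != n:
        raise ValueError("cluster_fn returned the wrong number of labels")

    rng = np.random.default_rng(seed)
    M = np.zeros((n, n), dtype=np.int64)
    I = np.zeros((n, n), dtype=np.int64)
    failures = 0
    iterations = []
    for _ in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        try:
            labels = np.asarray(cluster_fn(idx))
            if len(labels) != m:
                raise ValueError("label length mismatch")
        except Exception as exc:  # noqa: BLE001 - failures are counted, not fatal
            failures += 1
            log.debug("bootstrap iteration failed: %s", exc)
            continue
        M[np.ix_(idx, idx)] += 1
        for lab in np.unique(labels):
            members = idx[labels == lab]
            I[np.ix_(members, members)] += 1
        if store_iterations:
            iterations.append((idx.copy(), labels.copy()))
    if failures > max_failure_fraction * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap iterations failed")

    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(M > 0, I / np.maximum(M, 1), np.nan)
    return ConsensusResult(ids, reference, M, I, C, n_boot, fraction,
                           n_failures=failures, iterations=iterations)


def _stability_verdict(cluster_id: int, values: np.ndarray, n_members: int, *,
                       threshold: float = 0.5, alpha: float = 0.05,
                       shapiro_max: int = 5000, seed: int = 0) -> StabilityVerdict:
    values = np.asarray(values, dtype=float)
    n_pairs = len(values)
    base = dict(cluster_id=int(cluster_id), n_members=int(n_members),
                n_pairs=n_pairs)
    if n_members < 2:
        return StabilityVerdict(**base, mean_consensus=np.nan,
                                median_consensus=np.nan, normality_p=None,
                                test_used="none", test_p=None, stable=False,
                                reason="no pairs")
    if n_pairs < 3:
        return StabilityVerdict(
            **base,
            mean_consensus=float(values.mean()) if n_pairs else np.nan,
            median_consensus=float(np.median(values)) if n_pairs else np.nan,
            normality_p=None, test_used="none", test_p=None, stable=False,
            reason="insufficient pairs")
    mean_c = float(values.mean())
    median_c = float(np.median(values))
    if values.std(ddof=1) == 0.0:
        # constant sample: the location tests are undefined; decide directly
        stable = values[0] > threshold
        return StabilityVerdict(**base, mean_consensus=mean_c,
                                median_consensus=median_c, normality_p=None,
                                test_used="none", test_p=None, stable=bool(stable),
                                reason=f"constant at {values[0]:g}")
    sample = values
    if n_pairs > shapiro_max:
        rng = np.random.default_rng(seed)
        sample = rng.choice(values, size=shapiro_max, replace=False)
    sw_p = float(stats.shapiro(sample).pvalue)
    if sw_p > alpha:
        t_p = float(stats.ttest_1samp(values, threshold, alternative="greater").pvalue)
        stable = mean_c > threshold and t_p < alpha
        return StabilityVerdict(**base, mean_consensus=mean_c,
                                median_consensus=median_c, normality_p=sw_p,
                                test_used="t", test_p=t_p, stable=bool(stable))
    w_p = float(stats.wilcoxon(values - threshold, alternative="greater").pvalue)
    stable = median_c > threshold and w_p < alpha
    return StabilityVerdict(**base, mean_consensus=mean_c,
                            median_consensus=median_c, normality_p=sw_p,
                            test_used="wilcoxon", test_p=w_p, stable=bool(stable))


def stability_from_consensus(C: np.ndarray, labels: np.ndarray, *,
                             threshold: float = 0.5, alpha: float = 0.05,
                             shapiro_max: int = 5000, seed: int = 0
                             ) -> list[StabilityVerdict]:
    """Per-cluster verdicts from any consensus-valued similarity matrix.

    For each reference cluster the within-cluster, defined (non-NaN)
    upper-triangle consensus values are tested against the 0.5 threshold.
    """
    C = np.asarray(C, dtype=float)
    labels = np.asarray(labels)
    verdicts = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        iu = np.triu_indices(len(members), k=1)
        vals = C[np.ix_(members, members)][iu]
        vals = vals[~np.isnan(vals)]
        verdicts.append(_stability_verdict(lab, vals, len(members),
                                           threshold=threshold, alpha=alpha,
                                           shapiro_max=shapiro_max, seed=seed))
    return verdicts


def cluster_stability(result: ConsensusResult, *, threshold: float = 0.5,
                      alpha: float = 0.05, shapiro_max: int = 5000,
                      seed: int = 0) -> list[StabilityVerdict]:
    """Stability verdicts for the reference clusters of a consensus run."""
    return stability_from_consensus(result.C, result.reference_labels,
                                    threshold=threshold, alpha=alpha,
                                    shapiro_max=shapiro_max, seed=seed)
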