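"""Feature-table preprocessing and derived microbiome measures.

Metagenome side: total sum scaling, mean-abundance (0.005 % of total) and
prevalence (10 % non-zero) filters with explicit exclusion of flagged
(environmental / unassigned) taxa, the Firmicutes/Bacteroidetes phylum
ratio, Shannon diversity averaged over repeated rarefactions to the
dataset-minimum depth, and analytic (hypergeometric) expected richness.

Metabolome side: QC-injection relative-standard-deviation filtering
(drop > 30 %) and loess-based run-order drift normalization against the QC
trend.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    n_features_in: int
    n_features_out: int
    dropped_flagged: list = field(default_factory=list)
    dropped_low_abundance: list = field(default_factory=list)
    dropped_low_prevalence: list = field(default_factory=list)
    dropped_high_rsd: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_features_in": self.n_features_in,
            "n_features_out": self.n_features_out,
            "dropped_flagged": list(self.dropped_flagged),
            "dropped_low_abundance": list(self.dropped_low_abundance),
            "dropped_low_prevalence": list(self.dropped_low_prevalence),
            "dropped_high_rsd": list(self.dropped_high_rsd),
        }


def tss_scale(counts: pd.DataFrame) -> pd.DataFrame:
    """Total sum scaling: divide each row by its total.

    Idempotent on already-scaled rows; raises naming the sample on a
    zero-total row.
    """
    totals = counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total rows: {list(zero.index)}")
    return counts.div(totals, axis=0)


def filter_features(rel: pd.DataFrame, *, mean_threshold: float = 5e-5,
                    prevalence_threshold: float = 0.10,
                    flags: pd.Series | None = None
                    ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Keep features that are unflagged, sufficiently abundant, and prevalent.

    A feature is retained iff it is not flagged (environmental/unassigned),
    its mean relative abundance is >= ``mean_threshold`` (default 0.005 %
    of total), and it is non-zero in at least ``prevalence_threshold`` of
    participants. The first failing rule claims a dropped feature
    (flagged -> abundance -> prevalence).
    """
    for name, t in (("mean_threshold", mean_threshold),
                    ("prevalence_threshold", prevalence_threshold)):
        if not 0.0 < t < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {t}")
    report = PreprocessReport(n_features_in=rel.shape[1], n_features_out=0)
    flagged = set()
    if flags is not None:
        flagged = set(flags.index[~flags.isin(["ok"])]) & set(rel.columns)
    mean_ab = rel.mean(axis=0)
    prevalence = (rel > 0).mean(axis=0)
    keep = []
    for f in rel.columns:
        if f in flagged:
            report.dropped_flagged.append(f)
        elif mean_ab[f] < mean_threshold:
            report.dropped_low_abundance.append(f)
        elif prevalence[f] < prevalence_threshold:
            report.dropped_low_prevalence.append(f)
        else:
            keep.append(f)
    report.n_features_out = len(keep)
    return rel[keep], report


def fb_ratio(phylum_rel: pd.DataFrame, *, firmicutes: str = "Firmicutes",
             bacteroidetes: str = "Bacteroidetes",
             zero_policy: str = "nan") -> pd.Series:
    """Firmicutes / Bacteroidetes relative-abundance ratio per participant.

    ``zero_policy`` governs Bacteroidetes == 0: "nan" flags the ratio
    missing, "inf" reports infinity. Division by zero is never silent.
    """
    for col in (firmicutes, bacteroidetes):
        if col not in phylum_rel.columns:
            raise KeyError(f"phylum table lacks column {col!r}")
    f = phylum_rel[firmicutes].astype(float)
    b = phylum_rel[bacteroidetes].astype(float)
    out = pd.Series(np.nan, index=phylum_rel.index, name="fb_ratio")
    ok = b > 0
    out[ok] = f[ok] / b[ok]
    if (~ok).any():
        log.warning("Bacteroidetes = 0 for %d participants; ratio flagged %s",
                    int((~ok).sum()), zero_policy)
        if zero_policy == "inf":
            out[~ok] = np.inf
        elif zero_policy != "nan":
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
    return out


def _check_integer_counts(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise ValueError("counts must be non-negative integers")
    return np.round(arr).astype(np.int64)


def rarefied_shannon(counts: pd.DataFrame, *, n_reps: int = 100,
                     seed: int = 0, depth: int | None = None) -> pd.Series:
    """Mean Shannon diversity over repeated rarefactions.

    Each row is subsampled without replacement to the dataset-minimum depth
    (or ``depth``), H = -sum p ln p is computed on the non-zero
    proportions, and the mean over ``n_reps`` draws is returned.
    """
    arr = _check_integer_counts(counts)
    totals = arr.sum(axis=1)
    if totals.min() < 1:
        raise ValueError("every sample needs at least one count")
    d = int(totals.min()) if depth is None else int(depth)
    if d > totals.min():
        raise ValueError("depth exceeds the minimum sample total")
    rng = np.random.default_rng(seed)
    out = np.zeros(arr.shape[0])
    for i in range(arr.shape[0]):
        row = arr[i]
        acc = 0.0
        for _ in range(n_reps):
            sub = rng.multivariate_hypergeometric(row, d)
            p = sub[sub > 0] / d
            acc += float(-(p * np.log(p)).sum())
        out[i] = acc / n_reps
    return pd.Series(out, index=counts.index, name="shannon")


def expected_richness(counts: pd.DataFrame, depth: int) -> pd.Series:
    """Analytic rarefaction: E[S] = sum_k [1 - C(N-N_k, d) / C(N, d)].

    The hypergeometric expectation of the number of taxa observed in a
    without-replacement subsample of ``depth`` reads per sample.
    """
    arr = _check_integer_counts(counts)
    totals = arr.sum(axis=1)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if (depth > totals).any():
        bad = counts.index[depth > totals]
        raise ValueError(f"depth {depth} exceeds total for samples {list(bad)}")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.zeros(arr.shape[0])
    for i in range(arr.shape[0]):
        N = totals[i]
        Nk = arr[i][arr[i] > 0]
        prob_absent = np.zeros(len(Nk))
        feasible = (N - Nk) >= depth
        prob_absent[feasible] = np.exp(
            log_choose(N - Nk[feasible], depth) - log_choose(N, depth)
        )
        out[i] = float((1.0 - prob_absent).sum())
    return pd.Series(out, index=counts.index, name="expected_richness")


def qc_rsd_filter(intensities: pd.DataFrame, qc_mask: pd.Series, *,
                  rsd_threshold: float = 30.0
                  ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop features with QC relative standard deviation above the threshold.

    RSD = 100 * sd / mean over the QC injections; features with
    RSD strictly greater than ``rsd_threshold`` (percent) are removed.
    Features whose QC mean is zero are dropped as unmeasurable.
    """
    qc_mask = qc_mask.reindex(intensities.index).fillna(False).astype(bool)
    qc = intensities.loc[qc_mask]
    if len(qc) < 3:
        raise ValueError("need at least 3 QC rows")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    report = PreprocessReport(n_features_in=intensities.shape[1], n_features_out=0)
    keep = []
    for f in intensities.columns:
        if mean[f] == 0:
            report.dropped_high_rsd.append(f)
            log.warning("feature %s dropped: zero-mean QC", f)
            continue
        rsd = 100.0 * sd[f] / mean[f]
        if rsd > rsd_threshold:
            report.dropped_high_rsd.append(f)
        else:
            keep.append(f)
    report.n_features_out = len(keep)
    return intensities[keep], report


def runorder_normalize(intensities: pd.DataFrame, injection_order: pd.Series,
                       qc_mask: pd.Series, *, span: float = 0.75) -> pd.DataFrame:
    """Loess run-order normalization against the QC intensity trend.

    Per feature, a locally weighted regression of QC intensity on
    injection order is fitted; every sample is divided by the trend value
    interpolated at its order and rescaled to the feature's
    pre-normalization median. With fewer than 4 QC points the trend
    degenerates to median-centering (warned).
    """
    order = injection_order.reindex(intensities.index).astype(float)
    qc_mask = qc_mask.reindex(intensities.index).fillna(False).astype(bool)
    x_qc = order[qc_mask].to_numpy()
    x_all = order.to_numpy()
    out = intensities.copy().astype(float)
    few_qc = len(x_qc) < 4
    if few_qc:
        log.warning("fewer than 4 QC points: falling back to median-centering")
    for f in intensities.columns:
        y = intensities[f].to_numpy(dtype=float)
        med = float(np.median(y))
        if few_qc:
            qc_level = float(np.median(y[qc_mask.to_numpy()])) if qc_mask.any() else med
            trend = np.full_like(y, qc_level if qc_level > 0 else 1.0)
        else:
            y_qc = intensities.loc[qc_mask, f].to_numpy(dtype=float)
            trend = lowess(y_qc, x_qc, frac=span, xvals=x_all)
            trend = np.clip(trend, np.max(trend) * 1e-6, None)
        corrected = y / trend
        cmed = float(np.median(corrected))
        if cmed > 0:
            corrected *= med / cmed
        out[f] = corrected
    return out


def phylum_table(rel: pd.DataFrame, lineages: pd.Series) -> pd.DataFrame:
    """Aggregate TSS-scaled taxa to phylum level using lineage strings."""

    def phylum_of(lineage: str) -> str:
        for part in str(lineage).split(";"):
            part = part.strip()
            if part.startswith("p__"):
                return part[3:]
        return "unknown"

    phyla = rel.columns.to_series().map(lambda c: phylum_of(lineages.get(c, "")))
    return rel.T.groupby(phyla).sum().T
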