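"""Differential abundance and over-representation analysis.

Gene (compositional count) contrasts follow the Dirichlet-Monte-Carlo CLR
scheme: each of ``n_mc`` instances draws per-sample proportions from
Dirichlet(counts + 0.5), CLR-transforms them and runs a per-feature
Welch's t-test; the expected p-value (mean over instances) is BH-adjusted
across features, and the reported effect is the median over instances of
the between-group median CLR difference scaled by the larger within-group
dispersion.

Metabolite contrasts use a robust volcano rule: Wilcoxon rank-sum p-values
(BH-adjusted) combined with a kernel-weighted log2 fold change computed
from Tukey-biweight locations; a feature is called only when p_adj < 0.05
and |LFC| > 1.

Over-representation of feature sets is a hypergeometric upper-tail test
against a user-supplied background, BH-adjusted, with direction-specific
significance thresholds (0.05 for gene pathways, 0.1 for metabolite sets).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _two_groups(groups: pd.Series) -> tuple[np.ndarray, np.ndarray, list]:
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a = groups.index[groups == levels[0]]
    b = groups.index[groups == levels[1]]
    return a, b, levels


def aldex_clr_test(counts: pd.DataFrame, groups: pd.Series, *, n_mc: int = 128,
                   seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Dirichlet-Monte-Carlo CLR Welch tests with BH correction.

    ``effect`` > 0 means higher in the second (alphabetically later) group
    level. Calls require p_adj < ``alpha``.
    """
    a_ids, b_ids, levels = _two_groups(groups)
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("each group needs at least 3 samples")
    if n_mc < 16:
        log.warning("n_mc=%d is small; expected p-values will be noisy", n_mc)
    arr = counts.loc[list(a_ids) + list(b_ids)].to_numpy(dtype=float)
    if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
        raise ValueError("counts must be non-negative integers")
    na = len(a_ids)
    rng = np.random.default_rng(seed)
    alpha_dir = arr + 0.5
    p_sum = np.zeros(arr.shape[1])
    effects = np.empty((n_mc, arr.shape[1]))
    for t in range(n_mc):
        g = rng.standard_gamma(alpha_dir)
        logp = np.log(np.maximum(g, 1e-300))
        clr = logp - logp.mean(axis=1, keepdims=True)
        ca, cb = clr[:na], clr[na:]
        res = stats.ttest_ind(ca, cb, axis=0, equal_var=False)
        p_sum += np.nan_to_num(res.pvalue, nan=1.0)
        med_a = np.median(ca, axis=0)
        med_b = np.median(cb, axis=0)
        disp_a = np.median(np.abs(ca - med_a), axis=0)
        disp_b = np.median(np.abs(cb - med_b), axis=0)
        denom = np.maximum(np.maximum(disp_a, disp_b), 1e-12)
        effects[t] = (med_b - med_a) / denom
    p_raw = p_sum / n_mc
    effect = np.median(effects, axis=0)
    p_adj = bh_adjust(p_raw)
    call = np.where(p_adj < alpha, np.where(effect > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {"effect": effect, "p_raw": p_raw, "p_adj": p_adj, "call": call},
        index=pd.Index(counts.columns, name="feature_id"),
    ).assign(group_order=f"{levels[1]} vs {levels[0]}")


def biweight_location(x: np.ndarray, c: float = 6.0, max_iter: int = 10,
                      tol: float = 1e-8) -> float:
    """Tukey-biweight robust location (kernel-weighted mean)."""
    x = np.asarray(x, dtype=float)
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    if mad == 0:
        return m
    for _ in range(max_iter):
        u = (x - m) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        m_new = float((w * x).sum() / w.sum())
        if abs(m_new - m) < tol * max(1.0, abs(m)):
            return m_new
        m = m_new
    return m


def volcano_test(intensities: pd.DataFrame, groups: pd.Series, *,
                 lfc_threshold: float = 1.0, alpha: float = 0.05) -> pd.DataFrame:
    """Robust volcano calls: Wilcoxon rank-sum p + biweight-location log2 FC.

    A feature is "up" when p_adj < ``alpha`` AND LFC strictly >
    ``lfc_threshold`` (symmetric for "down"); LFC is log2 of the ratio of
    Tukey-biweight locations (second group level over first). Features
    with a non-positive location estimate are flagged untestable.
    """
    a_ids, b_ids, levels = _two_groups(groups)
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("each group needs at least 3 samples")
    A = intensities.loc[a_ids].to_numpy(dtype=float)
    B = intensities.loc[b_ids].to_numpy(dtype=float)
    nfeat = A.shape[1]
    p_raw = np.empty(nfeat)
    lfc = np.full(nfeat, np.nan)
    testable = np.ones(nfeat, dtype=bool)
    res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided")
    p_raw = np.asarray(res.pvalue, dtype=float)
    for j in range(nfeat):
        loc_a = biweight_location(A[:, j])
        loc_b = biweight_location(B[:, j])
        if loc_a <= 0 or loc_b <= 0:
            testable[j] = False
            continue
        lfc[j] = np.log2(loc_b / loc_a)
    p_raw[~testable] = np.nan
    p_adj = bh_adjust(p_raw)
    call = np.full(nfeat, "ns", dtype=object)
    call[~testable] = "untestable"
    sig = testable & (p_adj < alpha)
    call[sig & (lfc > lfc_threshold)] = "up"
    call[sig & (lfc < -lfc_threshold)] = "down"
    return pd.DataFrame(
        {"effect": lfc, "p_raw": p_raw, "p_adj": p_adj, "call": call},
        index=pd.Index(intensities.columns, name="feature_id"),
    ).assign(group_order=f"{levels[1]} vs {levels[0]}")


def ora(hits, background, sets: dict, *, q_threshold: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of named feature sets.

    ``hits`` must be a subset of ``background``; each set is intersected
    with the background before testing. An empty hit list returns an empty
    table (insufficient features for functional analysis).
    """
    background = set(background)
    hits = set(hits)
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    cols = ["set_size", "overlap", "p_raw", "q", "significant"]
    if not hits:
        log.info("empty hit list: no over-representation analysis possible")
        out = pd.DataFrame(columns=cols)
        out.index.name = "set_id"
        return out
    N, n_hit = len(background), len(hits)
    rows = []
    for set_id, members in sets.items():
        members = set(members) & background
        K = len(members)
        ov = len(members & hits)
        p = float(stats.hypergeom.sf(ov - 1, N, K, n_hit)) if K else np.nan
        rows.append({"set_id": set_id, "set_size": K, "overlap": ov, "p_raw": p})
    out = pd.DataFrame(rows).set_index("set_id")
    out["q"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    return out[cols]


def choose_reference_cluster(labels: pd.Series, is_control: pd.Series,
                             symptom_scores: pd.DataFrame,
                             tol: float = 1e-9) -> int:
    """Reference-cluster rule: lowest mean symptom burden, ties broken by
    the highest proportion of control participants."""
    df = pd.DataFrame({
        "label": labels,
        "control": is_control.astype(bool),
        "burden": symptom_scores.mean(axis=1),
    }).dropna()
    per = df.groupby("label").agg(burden=("burden", "mean"),
                                  control_prop=("control", "mean"))
    lo = per["burden"].min()
    candidates = per[per["burden"] <= lo + tol]
    return int(candidates["control_prop"].idxmax())


def read_gmt(path) -> dict:
    """Read a GMT-style set file: set_id <tab> description <tab> members..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets
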