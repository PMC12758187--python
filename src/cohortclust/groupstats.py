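"""Cluster-wise comparison of derived measures and cohort-level tests.

Each measure is compared across clusters with a normality-gated omnibus
test: Shapiro-Wilk per group (Bonferroni-corrected within the measure);
if every group passes, one-way ANOVA with Tukey HSD pairwise comparisons,
otherwise Kruskal-Wallis with Dunn's test and BH adjustment. Pairwise
tests run only when the omnibus is significant, and results are summarised
as a compact letter display (groups sharing a letter do not differ at the
0.05 level; insert-absorb construction).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    measure_id: str
    groups: list
    group_sizes: dict
    normality_p: dict              # group -> Bonferroni-corrected Shapiro p
    omnibus: str                   # "anova" | "kruskal-wallis"
    omnibus_p: float
    pairwise: dict = field(default_factory=dict)   # (g1, g2) -> adjusted p
    letters: dict = field(default_factory=dict)    # group -> letter string
    excluded_groups: list = field(default_factory=list)


def dunn_test(samples: dict) -> dict:
    """Dunn's rank-based pairwise z-tests with tie correction; raw p-values."""
    groups = list(samples)
    all_vals = np.concatenate([np.asarray(samples[g], dtype=float) for g in groups])
    n = len(all_vals)
    ranks = stats.rankdata(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    start = 0
    mean_ranks, sizes = {}, {}
    for g in groups:
        m = len(samples[g])
        mean_ranks[g] = ranks[start:start + m].mean()
        sizes[g] = m
        start += m
    var_base = n * (n + 1) / 12.0 - tie_term
    out = {}
    for g1, g2 in itertools.combinations(groups, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        out[(g1, g2)] = 2.0 * stats.norm.sf(abs(z))
    return out


def compact_letter_display(groups: list, significant_pairs: set) -> dict:
    """Insert-absorb compact letter display.

    Groups share at least one letter iff their pair is NOT in
    ``significant_pairs`` (unordered tuples).
    """
    sig = {frozenset(p) for p in significant_pairs}
    columns: list[set] = [set(groups)]
    for g1, g2 in itertools.combinations(groups, 2):
        if frozenset((g1, g2)) not in sig:
            continue
        for col in list(columns):
            if g1 in col and g2 in col:
                columns.remove(col)
                columns.append(col - {g1})
                columns.append(col - {g2})
        # absorb: drop columns contained in another
        columns = [c for c in columns
                   if not any(c < other for other in columns)]
        # deduplicate
        uniq = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    columns.sort(key=lambda c: sorted(str(g) for g in c))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i) if i < 26 else f"z{i}"
        for g in col:
            letters[g] += letter
    return letters


def compare_measure(values: pd.Series, group_labels: pd.Series, *,
                    alpha: float = 0.05, measure_id: str | None = None
                    ) -> ComparisonResult:
    """Normality-gated omnibus + post-hoc comparison of one measure.

    Groups with fewer than 3 non-missing members are excluded (warned).
    """
    measure_id = measure_id or (values.name or "measure")
    df = pd.DataFrame({"value": values, "group": group_labels}).dropna()
    sizes = df.groupby("group").size()
    excluded = list(sizes.index[sizes < 3])
    if excluded:
        log.warning("%s: excluding groups with < 3 members: %s", measure_id, excluded)
        df = df[~df["group"].isin(excluded)]
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 3 members")
    samples = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in groups}

    n_groups = len(groups)
    normality_p = {}
    all_normal = True
    for g in groups:
        x = samples[g]
        if np.ptp(x) == 0:
            p_adj = 0.0  # a constant group is trivially non-Gaussian
        else:
            p_adj = min(1.0, stats.shapiro(x).pvalue * n_groups)
        normality_p[g] = float(p_adj)
        if p_adj < alpha:
            all_normal = False

    if all_normal:
        omnibus = "anova"
        omnibus_p = float(stats.f_oneway(*samples.values()).pvalue)
    else:
        omnibus = "kruskal-wallis"
        omnibus_p = float(stats.kruskal(*samples.values()).pvalue)

    pairwise = {}
    if omnibus_p < alpha:
        if all_normal:
            res = stats.tukey_hsd(*[samples[g] for g in groups])
            for i, j in itertools.combinations(range(n_groups), 2):
                pairwise[(groups[i], groups[j])] = float(res.pvalue[i, j])
        else:
            raw = dunn_test(samples)
            keys = list(raw)
            from .differential import bh_adjust
            adj = bh_adjust(np.array([raw[k] for k in keys]))
            pairwise = {k: float(p) for k, p in zip(keys, adj)}
    sig_pairs = {k for k, p in pairwise.items() if p < alpha}
    letters = compact_letter_display(groups, sig_pairs)
    return ComparisonResult(
        measure_id=measure_id, groups=groups,
        group_sizes={g: int(sizes[g]) for g in groups},
        normality_p=normality_p, omnibus=omnibus, omnibus_p=omnibus_p,
        pairwise=pairwise, letters=letters, excluded_groups=excluded,
    )


def compare_measures(measures: pd.DataFrame, group_labels: pd.Series, *,
                     alpha: float = 0.05) -> dict:
    """Run compare_measure for every column; returns measure -> result."""
    return {col: compare_measure(measures[col], group_labels, alpha=alpha,
                                 measure_id=col)
            for col in measures.columns}


def cohort_tests(meta: pd.DataFrame, *, age_col: str = "age",
                 case_col: str = "is_case", sex_col: str = "is_female",
                 continuity_correction: bool = True) -> dict:
    """Cohort-level case/control comparisons.

    Welch two-sample t-test for age; chi-square test (with optional Yates
    continuity correction) on the 2x2 sex-by-case table. Warns when an
    expected cell count drops below 5.
    """
    case = meta[case_col].astype(bool)
    if case.all() or (~case).all():
        raise ValueError("need both cases and controls")
    out = {}
    if age_col in meta.columns:
        a = meta.loc[case, age_col].dropna()
        b = meta.loc[~case, age_col].dropna()
        t = stats.ttest_ind(a, b, equal_var=False)
        out["age"] = {"statistic": float(t.statistic), "p": float(t.pvalue),
                      "mean_case": float(a.mean()), "sd_case": float(a.std(ddof=1)),
                      "mean_control": float(b.mean()),
                      "sd_control": float(b.std(ddof=1))}
    if sex_col in meta.columns:
        table = pd.crosstab(case, meta[sex_col].astype(bool))
        chi2 = stats.chi2_contingency(table.to_numpy(),
                                      correction=continuity_correction)
        if (chi2.expected_freq < 5).any():
            log.warning("expected cell count < 5; consider an exact test")
        out["sex"] = {"statistic": float(chi2.statistic), "p": float(chi2.pvalue),
                      "table": table.to_numpy().tolist()}
    return out


def mean_sd(values) -> str:
    """'mean ± sd' reporting helper."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    return f"{v.mean():.3g} ± {v.std(ddof=1):.3g}"
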