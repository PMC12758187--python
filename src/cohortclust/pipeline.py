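"""End-to-end pipeline orchestration.

Stage order mirrors the study design: symptom data first (factor analysis,
then latent profile analysis with bootstrap stability), biological data
second (preprocessing, NEMO-style clustering with bootstrap stability),
then integration of the two consensus matrices, cluster-wise comparison of
derived measures, and differential/enrichment contrasts of a
DGBI-predominant cluster against the control-predominant reference.

Every stage writes its outputs under its own subdirectory of the run
directory and a manifest records seeds, parameters and content hashes so a
re-run with the same config reproduces identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, efa, groupstats, integrate, lpa, nemo, prep, stability
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort, write_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the study's stated settings."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # symptom side
    loading_threshold: float = 0.4
    rotation_starts: int = 30
    lpa_k_max: int = 8
    blrt_n_boot: int = 99
    blrt_alpha: float = 0.05
    # stability
    n_boot: int = 1000
    subsample_fraction: float = 0.75
    # omics prep
    abundance_threshold: float = 5e-5
    prevalence_threshold: float = 0.10
    qc_rsd_threshold: float = 30.0
    loess_span: float = 0.75
    rarefaction_reps: int = 100
    # nemo / integration
    k_nn: int | None = None
    k_range: tuple = (2, 15)
    # differential
    n_mc: int = 128
    lfc_threshold: float = 1.0
    q_genes: float = 0.05
    q_metabolites: float = 0.1
    # stage toggles
    run_integration: bool = True
    run_differential: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohort_raw = raw.pop("cohort", {})
        from .synthetic import CountBlockConfig, IntensityBlockConfig
        for key, klass in (("taxa_block", CountBlockConfig),
                           ("gene_block", CountBlockConfig)):
            if key in cohort_raw and isinstance(cohort_raw[key], dict):
                cohort_raw[key] = klass(**cohort_raw[key])
        if "metabolite_blocks" in cohort_raw:
            cohort_raw["metabolite_blocks"] = {
                k: IntensityBlockConfig(**v) if isinstance(v, dict) else v
                for k, v in cohort_raw["metabolite_blocks"].items()
            }
        cfg = cls(**{k: v for k, v in raw.items() if k != "k_range"},
                  k_range=tuple(raw.get("k_range", (2, 15))))
        cfg.cohort = CohortConfig(**cohort_raw)
        return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _prepare_count_block(fm, cfg: PipelineConfig):
    rel = prep.tss_scale(fm.values)
    flags = fm.feature_meta["flag"] if (fm.feature_meta is not None
                                        and "flag" in fm.feature_meta) else None
    filtered, report = prep.filter_features(
        rel, mean_threshold=cfg.abundance_threshold,
        prevalence_threshold=cfg.prevalence_threshold, flags=flags)
    return filtered, report


def _prepare_intensity_block(fm, cfg: PipelineConfig):
    sm = fm.sample_meta
    qc = sm["qc"].astype(bool)
    order = sm["injection_order"]
    normalized = prep.runorder_normalize(fm.values, order, qc, span=cfg.loess_span)
    kept, report = prep.qc_rsd_filter(normalized, qc,
                                      rsd_threshold=cfg.qc_rsd_threshold)
    study = kept.loc[~qc]
    return study, report


def run_pipeline(config: PipelineConfig, out_dir,
                 cohort: SyntheticCohort | None = None) -> dict:
    """Run all enabled stages; returns a results dictionary.

    Raises with the failing stage's name; outputs of completed stages are
    preserved on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}}
    results: dict = {}
    stage = "synthesize"
    try:
        if cohort is None:
            cohort = generate_cohort(config.cohort)
        write_cohort(cohort, out / "cohort")
        results["cohort"] = cohort
        ids = cohort.participant_ids

        stage = "factor_analysis"
        items = cohort.item_responses.values
        report = efa.suitability(items)
        model = efa.fit_efa(items, threshold=config.loading_threshold,
                            n_starts=config.rotation_starts, seed=config.seed)
        scores = model.scores.dropna()
        (out / "efa").mkdir(exist_ok=True)
        model.loadings.to_csv(out / "efa" / "loadings.tsv", sep="\t")
        scores.to_csv(out / "efa" / "scores.tsv", sep="\t")
        with open(out / "efa" / "suitability.json", "w") as fh:
            json.dump({"kmo": report.kmo_overall,
                       "bartlett_statistic": report.bartlett_statistic,
                       "bartlett_df": report.bartlett_df,
                       "bartlett_p": report.bartlett_p,
                       "dropped_items": model.dropped_items}, fh, indent=2)
        results["efa"] = model
        results["suitability"] = report

        stage = "symptom_clustering"
        X = scores.to_numpy()
        k_sym, blrt_table = lpa.blrt_select(
            X, config.lpa_k_max, n_boot=config.blrt_n_boot,
            alpha=config.blrt_alpha, seed=config.seed)
        sym_model = lpa.fit_lpa(X, max(k_sym, 1), seed=config.seed)
        assignments = lpa.assign_profiles(sym_model, ids=scores.index)
        (out / "lpa").mkdir(exist_ok=True)
        blrt_table.to_csv(out / "lpa" / "blrt.tsv", sep="\t", index=False)
        assignments.to_csv(out / "lpa" / "labels.tsv", sep="\t")
        results["k_symptom"] = k_sym
        results["symptom_labels"] = assignments["profile"]

        stage = "symptom_stability"
        if k_sym >= 2:
            def sym_cluster_fn(idx, _X=X, _k=k_sym, _seed=config.seed):
                return lpa.fit_lpa(_X[idx], _k, seed=_seed, n_restarts=3).labels
            res_sym = stability.bootstrap_consensus(
                scores.index, sym_cluster_fn, n_boot=config.n_boot,
                fraction=config.subsample_fraction, seed=config.seed)
        else:
            one = np.zeros(len(scores), dtype=int)
            res_sym = stability.bootstrap_consensus(
                scores.index, lambda idx: one[idx], n_boot=config.n_boot,
                fraction=config.subsample_fraction, seed=config.seed)
        sym_verdicts = stability.cluster_stability(res_sym, seed=config.seed)
        results["symptom_consensus"] = res_sym
        results["symptom_verdicts"] = sym_verdicts

        stage = "omics_prep"
        blocks, reports = {}, {}
        for name in ("taxa", "genes"):
            blocks[name], reports[name] = _prepare_count_block(
                cohort.omics_blocks[name], config)
        for name, fm in cohort.omics_blocks.items():
            if name in ("taxa", "genes"):
                continue
            blocks[name], reports[name] = _prepare_intensity_block(fm, config)
        (out / "prep").mkdir(exist_ok=True)
        with open(out / "prep" / "reports.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in reports.items()}, fh, indent=2)
        results["blocks"] = blocks
        results["prep_reports"] = reports

        taxa_fm = cohort.omics_blocks["taxa"]
        rel = prep.tss_scale(taxa_fm.values)
        phyl = prep.phylum_table(rel, taxa_fm.feature_meta["lineage"])
        measures = pd.DataFrame({
            "fb_ratio": prep.fb_ratio(phyl) if {"Firmicutes", "Bacteroidetes"}
            <= set(phyl.columns) else np.nan,
            "shannon": prep.rarefied_shannon(taxa_fm.values,
                                             n_reps=config.rarefaction_reps,
                                             seed=config.seed),
            "expected_richness": prep.expected_richness(
                taxa_fm.values, int(taxa_fm.values.sum(axis=1).min())),
        })
        measures.to_csv(out / "prep" / "microbiome_measures.tsv", sep="\t")
        results["measures"] = measures

        stage = "biological_clustering"
        bio_labels, merged_sim, k_bio = nemo.nemo_pipeline(
            blocks, cohort.modality_mask, k_nn=config.k_nn,
            k_range=config.k_range, seed=config.seed)
        (out / "nemo").mkdir(exist_ok=True)
        bio_labels.to_csv(out / "nemo" / "labels.tsv", sep="\t")
        results["k_biological"] = k_bio
        results["biological_labels"] = bio_labels

        stage = "biological_stability"
        bio_ids = merged_sim.index

        def bio_cluster_fn(idx, _S=merged_sim.to_numpy(), _k=k_bio,
                           _seed=config.seed):
            sub = _S[np.ix_(idx, idx)]
            return nemo.spectral_cluster(sub, _k, seed=_seed, n_init=10)

        res_bio = stability.bootstrap_consensus(
            bio_ids, bio_cluster_fn, n_boot=config.n_boot,
            fraction=config.subsample_fraction, seed=config.seed + 1)
        results["biological_consensus"] = res_bio
        results["biological_verdicts"] = stability.cluster_stability(
            res_bio, seed=config.seed)

        if config.run_integration:
            stage = "integration"
            integ = integrate.integrate(res_sym, res_bio, k_range=config.k_range,
                                        seed=config.seed)
            (out / "integration").mkdir(exist_ok=True)
            pd.DataFrame(integ.C_int, index=integ.participant_ids,
                         columns=integ.participant_ids).to_csv(
                out / "integration" / "consensus.tsv", sep="\t")
            pd.Series(integ.labels, index=integ.participant_ids,
                      name="integrated_cluster").to_csv(
                out / "integration" / "labels.tsv", sep="\t")
            results["integration"] = integ

            stage = "cluster_measures"
            labels = pd.Series(integ.labels, index=integ.participant_ids)
            stable_ids = {v.cluster_id for v in integ.verdicts if v.stable}
            usable = labels[labels.isin(stable_ids)]
            shared = measures.index.intersection(usable.index)
            if len(stable_ids) >= 2 and len(shared) > 6:
                comparisons = {}
                for col in measures.columns:
                    try:
                        comparisons[col] = groupstats.compare_measure(
                            measures.loc[shared, col], usable.loc[shared],
                            measure_id=col)
                    except ValueError as exc:
                        log.warning("measure %s not comparable: %s", col, exc)
                results["comparisons"] = comparisons

        if config.run_differential:
            stage = "differential"
            if not config.run_integration:
                raise RuntimeError(
                    "differential stage needs integration outputs; enable "
                    "run_integration or disable run_differential")
            integ = results["integration"]
            labels = pd.Series(integ.labels, index=integ.participant_ids)
            is_control = cohort.participants["diagnosis"].eq("control")
            ref = differential.choose_reference_cluster(
                labels, is_control.loc[labels.index],
                scores.loc[scores.index.intersection(labels.index)])
            stable_ids = {v.cluster_id for v in integ.verdicts if v.stable}
            per_cluster = {}
            counts = cohort.omics_blocks["genes"].values
            for lab in sorted(stable_ids - {ref}):
                sel = labels[labels.isin([ref, lab])]
                shared = counts.index.intersection(sel.index)
                grp = sel.loc[shared].map({ref: "a_ref", lab: "b_test"})
                if (grp == "a_ref").sum() < 3 or (grp == "b_test").sum() < 3:
                    continue
                per_cluster[lab] = differential.aldex_clr_test(
                    counts.loc[shared], grp, n_mc=config.n_mc, seed=config.seed)
            results["reference_cluster"] = ref
            results["gene_differential"] = per_cluster
            (out / "differential").mkdir(exist_ok=True)
            for lab, table in per_cluster.items():
                table.to_csv(out / "differential" / f"genes_cluster{lab}.tsv",
                             sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    for path in sorted(out.rglob("*.tsv")):
        manifest["stages"].setdefault(path.parent.name, {})[path.name] = \
            _hash_file(path)
    manifest["config"] = dataclasses.asdict(config)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
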