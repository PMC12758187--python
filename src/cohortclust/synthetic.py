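"""Synthetic cohort generator with planted symptom and multi-omic structure.

Emulates the data layout of a cross-sectional gut-brain-interaction cohort:

* per-participant symptom questionnaire items generated from a Gaussian
  factor model whose factor scores follow a Gaussian mixture with shared
  identity covariance (the latent-profile structure downstream stages must
  recover);
* compositional count blocks (taxa, KEGG-ortholog gene abundances) drawn
  from a Dirichlet-multinomial with cluster-specific log2 fold shifts on a
  designated subset of features;
* log-normal metabolite intensity blocks with cluster shifts, a smooth
  multiplicative injection-order drift and periodic pooled-QC injections;
* per-modality missingness with a guard that keeps at least one modality
  per participant.

Every quantity is reproducible from one integer seed: the seed feeds a
:class:`numpy.random.SeedSequence` and each block consumes an independent
child stream, so enabling or disabling one block never perturbs another.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

MODALITIES = ("taxa", "genes", "fecal_mx", "plasma_mx")


@dataclass
class CountBlockConfig:
    """Dirichlet-multinomial count block (taxa or gene abundances)."""

    n_features: int = 200
    n_shifted: int = 20
    log2_shift: float = 2.0
    depth_mean: int = 50_000
    concentration: float = 300.0  # Dirichlet overdispersion (larger = tighter)


@dataclass
class IntensityBlockConfig:
    """Log-normal LC-MS intensity block with QC injections and drift."""

    n_features: int = 150
    n_shifted: int = 15
    log2_shift: float = 2.0
    qc_every: int = 10           # one pooled QC per this many injections
    drift_amplitude: float = 0.3  # relative intensity change across the run
    noise_sd: float = 0.8         # log2-scale biological + technical spread


@dataclass
class CohortConfig:
    """Study-condition parameters for one synthetic cohort.

    ``factor_separation`` is the symmetric effect size between symptom
    profiles in within-cluster SD units: cluster means sit at the vertices
    of a regular simplex with edge length ``2 * factor_separation``, so
    each mean is ``factor_separation`` SDs from the midpoint of any pair.
    """

    n_participants: int = 300
    n_clusters_symptom: int = 3
    n_clusters_biological: int = 3
    concordance: float = 0.9
    n_factors: int = 3
    factor_separation: float = 3.0
    n_items_per_factor: int = 6
    loading_mean: float = 0.8
    taxa_block: CountBlockConfig = field(default_factory=CountBlockConfig)
    gene_block: CountBlockConfig = field(
        default_factory=lambda: CountBlockConfig(
            n_features=400, n_shifted=40, log2_shift=2.0, depth_mean=100_000
        )
    )
    metabolite_blocks: dict = field(
        default_factory=lambda: {
            "fecal_mx": IntensityBlockConfig(),
            "plasma_mx": IntensityBlockConfig(n_features=120, n_shifted=12),
        }
    )
    missing_rate_per_modality: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_participants": self.n_participants,
            "n_clusters_symptom": self.n_clusters_symptom,
            "n_clusters_biological": self.n_clusters_biological,
            "n_factors": self.n_factors,
            "n_items_per_factor": self.n_items_per_factor,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError(f"concordance must be in [0, 1], got {self.concordance}")
        if not 0.0 <= self.missing_rate_per_modality < 1.0:
            raise ValueError("missing_rate_per_modality must be in [0, 1)")
        for name, block in self.count_blocks().items():
            if block.n_shifted > block.n_features:
                raise ValueError(f"{name}: n_shifted > n_features")
        for name, block in self.metabolite_blocks.items():
            if block.n_shifted > block.n_features:
                raise ValueError(f"{name}: n_shifted > n_features")

    def count_blocks(self) -> dict:
        return {"taxa": self.taxa_block, "genes": self.gene_block}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticCohort:
    """Generated cohort with planted ground truth."""

    participants: pd.DataFrame        # diagnosis, symptom_cluster, biological_cluster
    factor_scores: pd.DataFrame       # true (generating) factor scores
    item_responses: FeatureMatrix
    omics_blocks: dict                # name -> FeatureMatrix (QC rows included for mx)
    modality_mask: pd.DataFrame       # participant x modality, True = measured
    config: CohortConfig

    @property
    def participant_ids(self) -> pd.Index:
        return self.participants.index


def _cluster_means(k: int, n_dims: int, separation: float) -> np.ndarray:
    """Regular-simplex cluster means with edge length 2 * separation.

    The k vertices live in a (k-1)-dimensional subspace (the centred rows
    of the identity, orthonormalised), scaled so every pair of means is
    exactly ``2 * separation`` apart, then embedded in the factor space.
    When n_dims < k - 1 the simplex is projected onto the available axes
    and pairwise distances shrink accordingly.
    """
    if k == 1 or separation == 0:
        return np.zeros((k, n_dims))
    V = np.eye(k) - 1.0 / k                      # centred simplex, rank k-1
    # orthonormal coordinates of the (k-1)-dim subspace
    U, s, _ = np.linalg.svd(V, full_matrices=False)
    coords = U[:, : k - 1] * s[: k - 1]          # pairwise distance sqrt(2)
    coords *= (2.0 * separation) / np.sqrt(2.0)
    means = np.zeros((k, n_dims))
    d = min(n_dims, k - 1)
    means[:, :d] = coords[:, :d]
    return means - means.mean(axis=0)


def _planted_effects(rng, n_features: int, n_shifted: int, log2_shift: float,
                     n_clusters: int) -> np.ndarray:
    """Cluster-by-feature log2 effect matrix; zero outside shifted features.

    Each cluster gets an independent Rademacher sign pattern over the
    shifted features, so every pair of clusters differs on roughly half of
    them.
    """
    effects = np.zeros((n_clusters, n_features))
    if n_shifted and log2_shift:
        signs = rng.choice([-1.0, 1.0], size=(n_clusters, n_shifted))
        effects[:, :n_shifted] = log2_shift * signs
    return effects


def _count_block(rng, cfg: CountBlockConfig, labels: np.ndarray, prefix: str,
                 ids: pd.Index, lineages: bool) -> FeatureMatrix:
    n = len(labels)
    k = int(labels.max()) + 1
    base = rng.normal(0.0, 1.5, size=cfg.n_features)
    effects = _planted_effects(rng, cfg.n_features, cfg.n_shifted, cfg.log2_shift, k)
    log_comp = base[None, :] + np.log(2.0) * effects[labels]
    comp = np.exp(log_comp)
    comp /= comp.sum(axis=1, keepdims=True)

    depths = rng.poisson(cfg.depth_mean, size=n)
    depths = np.maximum(depths, cfg.n_features)  # guard: never empty rows
    counts = np.empty((n, cfg.n_features), dtype=np.int64)
    for i in range(n):
        p = rng.dirichlet(comp[i] * cfg.concentration)
        counts[i] = rng.multinomial(depths[i], p)

    feat_ids = [f"{prefix}_{j:04d}" for j in range(cfg.n_features)]
    meta = pd.DataFrame(index=pd.Index(feat_ids, name="feature_id"))
    meta["shifted"] = [j < cfg.n_shifted for j in range(cfg.n_features)]
    meta["flag"] = "ok"
    if lineages:
        phyla = rng.choice(
            ["Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria"],
            size=cfg.n_features, p=[0.45, 0.3, 0.15, 0.1],
        )
        meta["lineage"] = [f"k__Bacteria;p__{p}" for p in phyla]
        # a few flagged features exercise the exclusion filters downstream
        n_flag = max(2, cfg.n_features // 100)
        flags = meta["flag"].to_numpy(dtype=object)
        flags[-n_flag:] = "unassigned"
        flags[-2 * n_flag:-n_flag] = "environmental"
        meta["flag"] = flags
    values = pd.DataFrame(counts, index=ids, columns=feat_ids)
    return FeatureMatrix(values, feature_meta=meta)


def _drift_curve(order_norm: np.ndarray, amplitude: float) -> np.ndarray:
    """Low-order polynomial multiplicative drift across the run, mean ~1."""
    t = order_norm - 0.5
    curve = 1.0 + amplitude * (t + 0.6 * (t ** 2 - 1.0 / 12.0))
    return np.maximum(curve, 0.05)


def _intensity_block(rng, cfg: IntensityBlockConfig, labels: np.ndarray,
                     prefix: str, ids: pd.Index) -> FeatureMatrix:
    n = len(labels)
    k = int(labels.max()) + 1
    base = rng.normal(18.0, 2.0, size=cfg.n_features)  # log2 intensity scale
    effects = _planted_effects(rng, cfg.n_features, cfg.n_shifted, cfg.log2_shift, k)

    # interleave pooled QC injections: position 1, then every qc_every-th slot
    study_order = rng.permutation(n)
    rows, is_qc = [], []
    si = 0
    pos = 0
    while si < n:
        if pos % cfg.qc_every == 0:
            rows.append(None)      # QC placeholder
            is_qc.append(True)
        else:
            rows.append(study_order[si])
            is_qc.append(False)
            si += 1
        pos += 1
    total = len(rows)
    order_norm = np.arange(total) / max(total - 1, 1)
    drift = _drift_curve(order_norm, cfg.drift_amplitude)
    # mild per-feature modulation of the shared drift shape
    feat_amp = rng.uniform(0.5, 1.5, size=cfg.n_features)

    log2_i = np.empty((total, cfg.n_features))
    sample_ids, qc_counter = [], 0
    for r, (row, qc) in enumerate(zip(rows, is_qc)):
        if qc:
            qc_counter += 1
            sample_ids.append(f"QC_{prefix}_{qc_counter:03d}")
            log2_i[r] = base + rng.normal(0.0, 0.05, size=cfg.n_features)
        else:
            sample_ids.append(ids[row])
            log2_i[r] = (base + effects[labels[row]]
                         + rng.normal(0.0, cfg.noise_sd, size=cfg.n_features))
        log2_i[r] += np.log2(1.0 + feat_amp * (drift[r] - 1.0))

    feat_ids = [f"{prefix}_{j:04d}" for j in range(cfg.n_features)]
    meta = pd.DataFrame(index=pd.Index(feat_ids, name="feature_id"))
    meta["shifted"] = [j < cfg.n_shifted for j in range(cfg.n_features)]
    values = pd.DataFrame(2.0 ** log2_i, index=pd.Index(sample_ids, name="participant_id"),
                          columns=feat_ids)
    sample_meta = pd.DataFrame(
        {"qc": is_qc, "injection_order": np.arange(1, total + 1)},
        index=values.index,
    )
    return FeatureMatrix(values, feature_meta=meta, sample_meta=sample_meta)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort with planted symptom and biological cluster structure.

    Raises
    ------
    ValueError
        If the configuration violates its invariants (fractions outside
        [0, 1], more shifted features than a block holds, ...).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("labels", "factors", "items", "taxa", "genes", "diagnosis", "missing",
             *config.metabolite_blocks),
            ss.spawn(7 + len(config.metabolite_blocks)),
        )
    }

    n = config.n_participants
    ids = pd.Index([f"P{i + 1:04d}" for i in range(n)], name="participant_id")
    rng = streams["labels"]
    sym = rng.integers(0, config.n_clusters_symptom, size=n)
    mapped = sym % config.n_clusters_biological
    concordant = rng.random(n) < config.concordance
    bio = np.where(concordant, mapped,
                   rng.integers(0, config.n_clusters_biological, size=n))

    # diagnosis: earlier symptom clusters are DGBI-heavy, the last control-heavy
    p_control = np.linspace(0.15, 0.8, config.n_clusters_symptom)
    is_control = streams["diagnosis"].random(n) < p_control[sym]
    participants = pd.DataFrame(
        {
            "diagnosis": np.where(is_control, "control", "dgbi"),
            "symptom_cluster": sym,
            "biological_cluster": bio,
        },
        index=ids,
    )

    means = _cluster_means(config.n_clusters_symptom, config.n_factors,
                           config.factor_separation)
    scores = means[sym] + streams["factors"].standard_normal((n, config.n_factors))
    factor_scores = pd.DataFrame(
        scores, index=ids,
        columns=[f"factor_{j + 1}" for j in range(config.n_factors)],
    )

    rng = streams["items"]
    item_ids, loadings_assign = [], []
    for j in range(config.n_factors):
        for i in range(config.n_items_per_factor):
            item_ids.append(f"item_f{j + 1}_{i + 1:02d}")
            loadings_assign.append(j)
    lam = np.clip(rng.normal(config.loading_mean, 0.05, size=len(item_ids)), 0.3, 0.95)
    unique_sd = np.sqrt(np.maximum(1.0 - lam ** 2, 1e-6))
    items = (scores[:, loadings_assign] * lam[None, :]
             + rng.standard_normal((n, len(item_ids))) * unique_sd[None, :])
    item_meta = pd.DataFrame(
        {"generating_factor": np.asarray(loadings_assign) + 1, "loading": lam},
        index=pd.Index(item_ids, name="feature_id"),
    )
    item_responses = FeatureMatrix(
        pd.DataFrame(items, index=ids, columns=item_ids), feature_meta=item_meta
    )

    omics = {
        "taxa": _count_block(streams["taxa"], config.taxa_block, bio, "taxon", ids,
                             lineages=True),
        "genes": _count_block(streams["genes"], config.gene_block, bio, "K", ids,
                              lineages=False),
    }
    for name, block_cfg in config.metabolite_blocks.items():
        omics[name] = _intensity_block(streams[name], block_cfg, bio, name, ids)

    mask = pd.DataFrame(True, index=ids, columns=list(omics))
    cohort = SyntheticCohort(participants, factor_scores, item_responses, omics,
                             mask, config)
    if config.missing_rate_per_modality > 0:
        cohort = apply_missingness(cohort, config.missing_rate_per_modality,
                                   seed=int(streams["missing"].integers(2 ** 31)))
    return cohort


def apply_missingness(cohort: SyntheticCohort, rate: float, seed: int) -> SyntheticCohort:
    """Mask participant-modality cells independently at the given rate.

    A guard keeps at least one modality per participant: if every draw for
    a participant comes up masked, the lowest-index modality is retained.
    Masked participants are removed from the corresponding block.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    mask = cohort.modality_mask.copy()
    draws = rng.random(mask.shape) >= rate  # True = keep
    keep = mask.to_numpy() & draws
    lost_all = ~keep.any(axis=1)
    keep[lost_all, 0] = True  # deterministic guard: lowest-index modality
    mask.iloc[:, :] = keep

    blocks = {}
    for name, fm in cohort.omics_blocks.items():
        kept_ids = mask.index[mask[name]]
        if fm.sample_meta is not None and "qc" in fm.sample_meta.columns:
            qc_ids = fm.sample_meta.index[fm.sample_meta["qc"].astype(bool)]
            row_ids = [i for i in fm.sample_ids if i in set(kept_ids) or i in set(qc_ids)]
        else:
            row_ids = [i for i in fm.sample_ids if i in set(kept_ids)]
        blocks[name] = fm.subset_samples(row_ids)
    return SyntheticCohort(cohort.participants, cohort.factor_scores,
                           cohort.item_responses, blocks, mask, cohort.config)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write all cohort tables as TSV plus the config echoed as YAML."""
    from pathlib import Path

    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out / "participants.tsv", sep="\t")
    cohort.factor_scores.to_csv(out / "true_factor_scores.tsv", sep="\t")
    cohort.item_responses.write_tsv(out / "item_responses.tsv")
    cohort.modality_mask.to_csv(out / "modality_mask.tsv", sep="\t")
    for name, fm in cohort.omics_blocks.items():
        fm.write_tsv(out / f"{name}.tsv")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=False)
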