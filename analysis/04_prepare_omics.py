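#!/usr/bin/env python
"""Preprocess the omic feature tables.

Count blocks (taxa, genes): total sum scaling, exclusion of flagged taxa,
0.005 % mean-abundance and 10 % prevalence filters. Metabolite blocks:
loess run-order normalization against the QC trend, then the 30 % QC-RSD
filter. Also derives the per-participant microbiome measures
(Firmicutes/Bacteroidetes ratio, 100x-rarefied Shannon diversity,
analytic expected richness).
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from cohortclust import prep
from cohortclust.containers import FeatureMatrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort_dir = args.out / "cohort"
    out = args.out / "prep"
    out.mkdir(parents=True, exist_ok=True)
    reports = {}

    for name in ("taxa", "genes"):
        fm = FeatureMatrix.read_tsv(cohort_dir / f"{name}.tsv")
        rel = prep.tss_scale(fm.values)
        flags = fm.feature_meta["flag"] if "flag" in fm.feature_meta else None
        kept, report = prep.filter_features(rel, flags=flags)
        kept.round(6).to_csv(out / f"{name}_filtered.tsv", sep="\t")
        reports[name] = report.to_dict()
        print(f"{name}: kept {report.n_features_out}/{report.n_features_in} "
              f"(flagged {len(report.dropped_flagged)}, "
              f"low-abundance {len(report.dropped_low_abundance)}, "
              f"low-prevalence {len(report.dropped_low_prevalence)})")

    for name in ("fecal_mx", "plasma_mx"):
        fm = FeatureMatrix.read_tsv(cohort_dir / f"{name}.tsv")
        qc = fm.sample_meta["qc"].astype(bool)
        norm = prep.runorder_normalize(fm.values,
                                       fm.sample_meta["injection_order"], qc)
        kept, report = prep.qc_rsd_filter(norm, qc)
        kept.loc[~qc].round(2).to_csv(out / f"{name}_normalized.tsv", sep="\t")
        reports[name] = report.to_dict()
        print(f"{name}: kept {report.n_features_out}/{report.n_features_in} "
              f"after run-order normalization "
              f"({len(report.dropped_high_rsd)} above 30% QC-RSD)")

    taxa = FeatureMatrix.read_tsv(cohort_dir / "taxa.tsv")
    rel = prep.tss_scale(taxa.values)
    phyl = prep.phylum_table(rel, taxa.feature_meta["lineage"])
    min_depth = int(taxa.values.sum(axis=1).min())
    measures = pd.DataFrame({
        "fb_ratio": prep.fb_ratio(phyl),
        "shannon": prep.rarefied_shannon(taxa.values, n_reps=100,
                                         seed=args.seed),
        "expected_richness": prep.expected_richness(taxa.values, min_depth),
    })
    measures.round(4).to_csv(out / "microbiome_measures.tsv", sep="\t")
    with open(out / "reports.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    print(f"microbiome measures (n={len(measures)}): "
          f"FB ratio median {measures['fb_ratio'].median():.2f}, "
          f"Shannon mean {measures['shannon'].mean():.2f}, "
          f"expected richness mean {measures['expected_richness'].mean():.1f} "
          f"at depth {min_depth}")


if __name__ == "__main__":
    main()
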