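#!/usr/bin/env python
"""Differential abundance and over-representation against the reference
cluster.

Picks the control-predominant, lowest-symptom-burden stable integrated
cluster as reference; contrasts each other stable cluster's gene counts
(Dirichlet-Monte-Carlo CLR Welch tests, 128 instances) and fecal
metabolite intensities (robust volcano: Wilcoxon + biweight log2 FC);
then runs hypergeometric over-representation of synthetic pathway sets,
up- and down-regulated features separately (q < 0.05 genes, q < 0.1
metabolites).
"""
import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cohortclust import differential
from cohortclust.containers import FeatureMatrix


def synthetic_gene_sets(features, set_size=20, seed=0):
    """Contiguous feature windows standing in for pathway membership."""
    rng = np.random.default_rng(seed)
    features = list(features)
    sets = {}
    for i in range(0, len(features) - set_size + 1, set_size // 2):
        sets[f"pathway_{len(sets) + 1:02d}"] = features[i:i + set_size]
    # plus a few random sets
    for j in range(5):
        sets[f"random_{j + 1}"] = list(rng.choice(features, set_size,
                                                  replace=False))
    return sets


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    labels = pd.read_csv(args.out / "integration" / "labels.tsv", sep="\t",
                         index_col=0)["integrated_cluster"]
    verdicts = json.loads((args.out / "integration" / "stability.json").read_text())
    stable = {v["cluster_id"] for v in verdicts if v["stable"]}
    meta = pd.read_csv(args.out / "cohort" / "participants.tsv", sep="\t",
                       index_col=0)
    scores = pd.read_csv(args.out / "efa" / "scores.tsv", sep="\t", index_col=0)

    usable = labels[labels.isin(stable)]
    ref = differential.choose_reference_cluster(
        usable, meta.loc[usable.index, "diagnosis"].eq("control"),
        scores.loc[usable.index])
    comp = meta.loc[usable.index, "diagnosis"].groupby(usable).apply(
        lambda s: (s == "control").mean())
    print(f"reference cluster: {ref} "
          f"(control proportion {comp[ref]:.2f}, lowest symptom burden)")

    genes = FeatureMatrix.read_tsv(args.out / "cohort" / "genes.tsv").values
    fecal = pd.read_csv(args.out / "prep" / "fecal_mx_normalized.tsv", sep="\t",
                        index_col=0)
    out = args.out / "differential"
    out.mkdir(parents=True, exist_ok=True)

    for lab in sorted(stable - {ref}):
        sel = usable[usable.isin([ref, lab])]
        shared = genes.index.intersection(sel.index)
        grp = sel.loc[shared].map({ref: "a_ref", lab: "b_test"})
        if (grp == "a_ref").sum() < 3 or (grp == "b_test").sum() < 3:
            print(f"cluster {lab}: too few participants for contrast, skipped")
            continue
        table = differential.aldex_clr_test(genes.loc[shared], grp, n_mc=128,
                                            seed=args.seed)
        n_up = (table["call"] == "up").sum()
        n_dn = (table["call"] == "down").sum()
        print(f"cluster {lab} vs {ref} (genes): {n_up} up, {n_dn} down "
              f"of {len(table)}")
        table.round(5).to_csv(out / f"genes_c{lab}_vs_c{ref}.tsv", sep="\t")

        sets = synthetic_gene_sets(table.index, seed=args.seed)
        for direction in ("up", "down"):
            hits = list(table.index[table["call"] == direction])
            ora = differential.ora(hits, list(table.index), sets,
                                   q_threshold=0.05)
            n_sig = 0 if ora.empty else int(ora["significant"].sum())
            print(f"  ORA {direction}: {len(hits)} hits -> "
                  f"{n_sig} significant sets (q < 0.05)")
            ora.round(5).to_csv(out / f"ora_genes_{direction}_c{lab}.tsv",
                                sep="\t")

        mx_shared = fecal.index.intersection(sel.index)
        mgrp = sel.loc[mx_shared].map({ref: "a_ref", lab: "b_test"})
        if (mgrp == "a_ref").sum() >= 3 and (mgrp == "b_test").sum() >= 3:
            volcano = differential.volcano_test(fecal.loc[mx_shared], mgrp)
            calls = volcano["call"].value_counts().to_dict()
            print(f"cluster {lab} vs {ref} (fecal metabolites): {calls}")
            volcano.round(5).to_csv(out / f"fecal_c{lab}_vs_c{ref}.tsv",
                                    sep="\t")


if __name__ == "__main__":
    main()
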