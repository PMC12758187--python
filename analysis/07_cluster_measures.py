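#!/usr/bin/env python
"""Compare derived measures across the stable integrated clusters.

Each microbiome measure and factor score is tested with the
normality-gated omnibus scheme (Shapiro-Wilk per cluster with Bonferroni;
ANOVA + Tukey HSD when all clusters look Gaussian, Kruskal-Wallis +
BH-adjusted Dunn otherwise) and summarised as a compact letter display.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from cohortclust import groupstats


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    labels = pd.read_csv(args.out / "integration" / "labels.tsv", sep="\t",
                         index_col=0)["integrated_cluster"]
    verdicts = json.loads((args.out / "integration" / "stability.json").read_text())
    stable = {v["cluster_id"] for v in verdicts if v["stable"]}
    usable = labels[labels.isin(stable)]
    print(f"comparing across {len(stable)} stable clusters "
          f"({len(usable)} participants; unstable clusters excluded)")

    measures = pd.read_csv(args.out / "prep" / "microbiome_measures.tsv",
                           sep="\t", index_col=0)
    scores = pd.read_csv(args.out / "efa" / "scores.tsv", sep="\t", index_col=0)
    table = measures.join(scores, how="inner")
    shared = table.index.intersection(usable.index)

    rows = []
    for col in table.columns:
        try:
            res = groupstats.compare_measure(table.loc[shared, col],
                                             usable.loc[shared], measure_id=col)
        except ValueError as exc:
            print(f"  {col}: skipped ({exc})")
            continue
        letters = " ".join(f"{g}:{res.letters[g]}" for g in res.groups)
        print(f"  {col}: {res.omnibus} p = {res.omnibus_p:.3g} -> {letters}")
        rows.append({"measure": col, "omnibus": res.omnibus,
                     "omnibus_p": res.omnibus_p, "letters": letters})
    out = args.out / "comparisons"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "measures.tsv", sep="\t", index=False)

    meta = pd.read_csv(args.out / "cohort" / "participants.tsv", sep="\t",
                       index_col=0)
    per_cluster = (meta.loc[usable.index, "diagnosis"]
                   .groupby(usable).value_counts().unstack(fill_value=0))
    print("diagnosis composition per stable cluster:")
    print(per_cluster.to_string())
    per_cluster.to_csv(out / "diagnosis_composition.tsv", sep="\t")


if __name__ == "__main__":
    main()
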