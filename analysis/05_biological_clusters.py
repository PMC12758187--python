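#!/usr/bin/env python
"""Neighborhood-based multi-omics clustering of the preprocessed blocks,
with eigengap cluster-count selection and bootstrap consensus stability.
Participants keep their membership as long as they share at least one
measured block with every co-clustered participant.
"""
import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cohortclust import nemo, stability


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-boot", type=int, default=200)
    args = ap.parse_args()

    prep_dir = args.out / "prep"
    blocks = {
        "taxa": pd.read_csv(prep_dir / "taxa_filtered.tsv", sep="\t", index_col=0),
        "genes": pd.read_csv(prep_dir / "genes_filtered.tsv", sep="\t", index_col=0),
        "fecal_mx": pd.read_csv(prep_dir / "fecal_mx_normalized.tsv", sep="\t",
                                index_col=0),
        "plasma_mx": pd.read_csv(prep_dir / "plasma_mx_normalized.tsv", sep="\t",
                                 index_col=0),
    }
    mask = pd.read_csv(args.out / "cohort" / "modality_mask.tsv", sep="\t",
                       index_col=0).astype(bool)
    labels, merged, k = nemo.nemo_pipeline(blocks, mask, seed=args.seed)
    print(f"eigengap selected {k} biological clusters over "
          f"{len(labels)} participants")
    print("cluster sizes:", labels.value_counts().sort_index().to_dict())

    S = merged.to_numpy()

    def cluster_fn(idx):
        return nemo.spectral_cluster(S[np.ix_(idx, idx)], k, seed=args.seed,
                                     n_init=10)

    res = stability.bootstrap_consensus(merged.index, cluster_fn,
                                        n_boot=args.n_boot, seed=args.seed + 1)
    verdicts = stability.cluster_stability(res)
    for v in verdicts:
        print(f"cluster {v.cluster_id}: n={v.n_members}, "
              f"mean consensus {v.mean_consensus:.3f}, "
              f"{'stable' if v.stable else 'UNSTABLE'}")

    out = args.out / "nemo"
    out.mkdir(parents=True, exist_ok=True)
    labels.to_csv(out / "labels.tsv", sep="\t")
    merged.round(4).to_csv(out / "merged_similarity.tsv", sep="\t")
    res.consensus_frame().round(4).to_csv(out / "consensus.tsv", sep="\t")
    with open(out / "stability.json", "w") as fh:
        json.dump([v.to_dict() for v in verdicts], fh, indent=2)


if __name__ == "__main__":
    main()
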