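#!/usr/bin/env python
"""Latent profile analysis of the factor scores with BLRT model selection,
followed by bootstrap pair-consensus stability of the chosen profiles.
"""
import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cohortclust import lpa, stability


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-boot", type=int, default=200)
    args = ap.parse_args()

    scores = pd.read_csv(args.out / "efa" / "scores.tsv", sep="\t", index_col=0)
    X = scores.to_numpy()
    k, blrt = lpa.blrt_select(X, k_max=5, n_boot=59, seed=args.seed,
                              n_restarts=5, boot_restarts=2)
    print("BLRT sequence:")
    print(blrt.round(4).to_string(index=False))
    print(f"selected profile count: {k}")

    model = lpa.fit_lpa(X, k, seed=args.seed)
    labels = lpa.assign_profiles(model, ids=scores.index)

    def cluster_fn(idx):
        return lpa.fit_lpa(X[idx], k, seed=args.seed, n_restarts=3).labels

    res = stability.bootstrap_consensus(scores.index, cluster_fn,
                                        n_boot=args.n_boot, seed=args.seed)
    verdicts = stability.cluster_stability(res)
    for v in verdicts:
        print(f"profile {v.cluster_id}: n={v.n_members}, "
              f"mean consensus {v.mean_consensus:.3f}, "
              f"{'stable' if v.stable else 'UNSTABLE'} ({v.test_used}"
              f"{'' if v.test_p is None else f', p={v.test_p:.3g}'})")

    out = args.out / "lpa"
    out.mkdir(parents=True, exist_ok=True)
    blrt.to_csv(out / "blrt.tsv", sep="\t", index=False)
    labels.to_csv(out / "labels.tsv", sep="\t")
    res.consensus_frame().round(4).to_csv(out / "consensus.tsv", sep="\t")
    with open(out / "stability.json", "w") as fh:
        json.dump([v.to_dict() for v in verdicts], fh, indent=2)


if __name__ == "__main__":
    main()
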