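#!/usr/bin/env python
"""Merged consensus integration of the symptom and biological clusterings.

Averages the two consensus matrices over shared participants, cuts the
complete-linkage tree of 1 - consensus, scans cluster counts with
silhouette and medoid-form Davies-Bouldin, and tests integrated-cluster
stability on the merged matrix. Also compares symptom-truth agreement of
each clustering level.
"""
import argparse
import json
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from cohortclust import integrate
from cohortclust.stability import ConsensusResult


def load_consensus(path: Path) -> ConsensusResult:
    """Rehydrate a stored consensus matrix (M/I counts not needed here)."""
    import numpy as np

    C = pd.read_csv(path, sep="\t", index_col=0)
    arr = C.to_numpy()
    defined = (~np.isnan(arr)).astype(int)
    return ConsensusResult(participant_ids=C.index,
                           reference_labels=np.zeros(len(C), dtype=int),
                           M=defined, I=np.zeros_like(defined), C=arr,
                           n_boot=1, subsample_fraction=0.75)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    res_sym = load_consensus(args.out / "lpa" / "consensus.tsv")
    res_bio = load_consensus(args.out / "nemo" / "consensus.tsv")
    integ = integrate.integrate(res_sym, res_bio, k_range=(2, 15),
                                seed=args.seed)
    sil = integ.silhouette_by_k
    dbi = integ.dbi_by_k
    print(f"integrated over {len(integ.participant_ids)} shared participants")
    print(f"selected k = {integ.k_selected} "
          f"(silhouette {sil[integ.k_selected]:.3f}, "
          f"DBI {dbi[integ.k_selected]:.3f}; criteria "
          f"{'agree' if integ.dbi_agrees else 'DISAGREE'})")
    curve = pd.DataFrame({"k": sorted(sil), "silhouette": [sil[k] for k in sorted(sil)],
                          "dbi": [dbi[k] for k in sorted(sil)]})
    print(curve.round(3).to_string(index=False))

    n_stable = sum(v.stable for v in integ.verdicts)
    print(f"{n_stable}/{len(integ.verdicts)} integrated clusters stable")
    for v in integ.verdicts:
        flag = "stable" if v.stable else f"UNSTABLE ({v.reason or v.test_used})"
        print(f"  cluster {v.cluster_id}: n={v.n_members}, "
              f"mean consensus {v.mean_consensus:.3f}, {flag}")

    truth = pd.read_csv(args.out / "cohort" / "participants.tsv", sep="\t",
                        index_col=0)
    shared = integ.participant_ids
    labels = pd.Series(integ.labels, index=shared)
    print("agreement with planted truths (ARI): "
          f"symptom {adjusted_rand_score(truth.loc[shared, 'symptom_cluster'], labels):.3f}, "
          f"biological {adjusted_rand_score(truth.loc[shared, 'biological_cluster'], labels):.3f}")

    out = args.out / "integration"
    out.mkdir(parents=True, exist_ok=True)
    labels.rename("integrated_cluster").to_csv(out / "labels.tsv", sep="\t")
    curve.to_csv(out / "selection_curve.tsv", sep="\t", index=False)
    pd.DataFrame(integ.C_int, index=shared, columns=shared).round(4).to_csv(
        out / "consensus.tsv", sep="\t")
    with open(out / "stability.json", "w") as fh:
        json.dump([v.to_dict() for v in integ.verdicts], fh, indent=2)


if __name__ == "__main__":
    main()
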