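import numpy as np
import pandas as pd
import pytest

from cohortclust import integrate, stability


def consensus_result(ids, C):
    C = np.asarray(C, dtype=float)
    n = len(ids)
    M = np.full((n, n), 10, dtype=int)
    return stability.ConsensusResult(
        participant_ids=pd.Index(ids), reference_labels=np.zeros(n, dtype=int),
        M=M, I=(np.nan_to_num(C) * 10).astype(int), C=C, n_boot=10,
        subsample_fraction=0.75)


def block_consensus(sizes, within=1.0, between=0.0):
    n = sum(sizes)
    C = np.full((n, n), between)
    start = 0
    for s in sizes:
        C[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(C, 1.0)
    return C


class TestMergeConsensus:
    def test_identical_inputs_idempotent(self):
        ids = list("ABCD")
        C = block_consensus([2, 2])
        r = integrate.merge_consensus(consensus_result(ids, C),
                                      consensus_result(ids, C))
        assert np.allclose(r.C_int, C)

    def test_elementwise_average(self):
        ids = list("AB")
        a = consensus_result(ids, [[1.0, 0.2], [0.2, 1.0]])
        b = consensus_result(ids, [[1.0, 0.8], [0.8, 1.0]])
        r = integrate.merge_consensus(a, b)
        assert r.C_int[0, 1] == pytest.approx(0.5)

    def test_commutative(self):
        ids = list("ABC")
        rng = np.random.default_rng(0)
        X = rng.random((3, 3))
        Ca, Cb = (X + X.T) / 2, np.eye(3)
        r1 = integrate.merge_consensus(consensus_result(ids, Ca),
                                       consensus_result(ids, Cb))
        r2 = integrate.merge_consensus(consensus_result(ids, Cb),
                                       consensus_result(ids, Ca))
        assert np.allclose(r1.C_int, r2.C_int)

    def test_restricts_to_intersection(self):
        a = consensus_result(list("ABC"), block_consensus([1, 2]))
        b = consensus_result(list("BCD"), block_consensus([2, 1]))
        r = integrate.merge_consensus(a, b)
        assert list(r.participant_ids) == ["B", "C"]

    def test_undefined_entry_uses_other_modality(self):
        ids = list("AB")
        Ca = np.array([[1.0, np.nan], [np.nan, 1.0]])
        Cb = np.array([[1.0, 0.6], [0.6, 1.0]])
        r = integrate.merge_consensus(consensus_result(ids, Ca),
                                      consensus_result(ids, Cb))
        assert r.C_int[0, 1] == pytest.approx(0.6)

    def test_empty_intersection_raises(self):
        a = consensus_result(list("AB"), np.eye(2))
        b = consensus_result(list("CD"), np.eye(2))
        with pytest.raises(ValueError):
            integrate.merge_consensus(a, b)


class TestCutConsensusTree:
    def test_two_perfect_blocks_recovered(self):
        C = block_consensus([4, 3])
        labels = integrate.cut_consensus_tree(C, 2)
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_hand_traced_complete_linkage_example(self):
        # distances: AB = CD = 0.1, all cross pairs 0.9 -> {A,B}, {C,D}
        D = np.full((4, 4), 0.9)
        D[0, 1] = D[1, 0] = 0.1
        D[2, 3] = D[3, 2] = 0.1
        np.fill_diagonal(D, 0.0)
        labels = integrate.cut_consensus_tree(1.0 - D, 2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_monotone_distance_transform_preserves_topology(self):
        rng = np.random.default_rng(5)
        X = rng.random((8, 8))
        C = np.clip((X + X.T) / 2, 0, 0.99)
        np.fill_diagonal(C, 1.0)
        base = integrate.cut_consensus_tree(C, 3)
        # squaring D = 1 - C preserves the distance ordering
        C2 = 1.0 - (1.0 - C) ** 2
        transformed = integrate.cut_consensus_tree(C2, 3)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(base, transformed) == 1.0

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            integrate.cut_consensus_tree(np.eye(3), 4)


def brute_force_silhouette(D, labels):
    n = len(labels)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestSelectK:
    def test_silhouette_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.random((9, 9))
        C = np.clip((X + X.T) / 2, 0, 0.99)
        np.fill_diagonal(C, 1.0)
        D = integrate._distance(C)
        for k in (2, 3, 4):
            labels = integrate.cut_consensus_tree(C, k)
            if len(set(labels)) < 2:
                continue
            from sklearn.metrics import silhouette_score
            assert silhouette_score(D, labels, metric="precomputed") == \
                pytest.approx(brute_force_silhouette(D, labels), abs=1e-12)

    def test_three_planted_blocks_selected_by_both_criteria(self):
        rng = np.random.default_rng(3)
        C = block_consensus([10, 12, 9], within=0.95, between=0.05)
        C = np.clip(C + rng.normal(0, 0.01, C.shape), 0, 1)
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        k, dbi, sil, agrees = integrate.select_k(C, (2, 8))
        assert k == 3
        assert min(dbi, key=dbi.get) == 3
        assert agrees

    def test_two_block_perfect_consensus_silhouette_is_one(self):
        C = block_consensus([5, 5])
        _, _, sil, _ = integrate.select_k(C, (2, 4))
        assert sil[2] == pytest.approx(1.0)

    def test_selection_is_a_fixed_point(self):
        C = block_consensus([8, 7, 6], within=0.9, between=0.1)
        k1, _, _, _ = integrate.select_k(C, (2, 8))
        _ = integrate.cut_consensus_tree(C, k1)
        k2, _, _, _ = integrate.select_k(C, (2, 8))
        assert k1 == k2


class TestIntegratedStability:
    def test_perfect_blocks_all_stable(self):
        C = block_consensus([6, 6])
        labels = integrate.cut_consensus_tree(C, 2)
        verdicts = integrate.integrated_stability(C, labels)
        assert all(v.stable for v in verdicts)

    def test_cross_modality_disagreement_cluster_unstable(self):
        rng = np.random.default_rng(7)
        n = 20
        C = np.clip(0.5 + rng.normal(0, 0.03, (n, n)), 0, 1)
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        verdicts = integrate.integrated_stability(C, np.zeros(n, dtype=int))
        assert not verdicts[0].stable

    def test_singleton_cluster_reason(self):
        C = block_consensus([4, 1])
        labels = np.array([0, 0, 0, 0, 1])
        verdicts = integrate.integrated_stability(C, labels)
        singleton = [v for v in verdicts if v.n_members == 1][0]
        assert not singleton.stable
        assert singleton.reason == "no pairs"
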