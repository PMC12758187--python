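import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from cohortclust import differential


def count_table(rng, n_per_group=15, n_features=40, shift_feature=None, fold=1.0,
                depth=5000):
    base = rng.lognormal(0, 1, n_features)
    rows = []
    for g in range(2):
        comp = base.copy()
        if shift_feature is not None and g == 1:
            comp[shift_feature] *= fold
        comp = comp / comp.sum()
        for _ in range(n_per_group):
            rows.append(rng.multinomial(depth, rng.dirichlet(comp * 300)))
    ids = [f"s{i}" for i in range(2 * n_per_group)]
    counts = pd.DataFrame(rows, index=ids,
                          columns=[f"g{j}" for j in range(n_features)])
    groups = pd.Series(["a"] * n_per_group + ["b"] * n_per_group, index=ids)
    return counts, groups


class TestBHAdjust:
    def test_hand_computed_step_up_example(self):
        p = np.array([0.005, 0.03, 0.04, 0.20, 0.90])
        adj = differential.bh_adjust(p)
        expected = [0.025, 0.2 / 3, 0.2 / 3, 0.25, 0.90]
        assert adj == pytest.approx(expected)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        assert (differential.bh_adjust(p) >= p - 1e-12).all()


class TestAldexCLR:
    def test_null_data_makes_no_calls(self):
        rng = np.random.default_rng(1)
        counts, groups = count_table(rng)
        table = differential.aldex_clr_test(counts, groups, n_mc=32, seed=0)
        assert (table["call"] == "ns").all()
        # expected p-values roughly uniform under the null
        assert table["p_raw"].mean() == pytest.approx(0.5, abs=0.15)

    def test_planted_eightfold_shift_called_with_correct_sign(self):
        rng = np.random.default_rng(2)
        counts, groups = count_table(rng, n_per_group=20, shift_feature=0,
                                     fold=8.0)
        table = differential.aldex_clr_test(counts, groups, n_mc=64, seed=0)
        assert table.loc["g0", "call"] == "up"     # higher in group b
        assert table.loc["g0", "effect"] > 0

    def test_scale_invariance_of_effects(self):
        rng = np.random.default_rng(3)
        counts, groups = count_table(rng, n_per_group=10, n_features=25)
        t1 = differential.aldex_clr_test(counts, groups, n_mc=32, seed=7)
        scaled = counts.copy()
        scaled.iloc[0] *= 4  # quadruple one sample's depth
        t2 = differential.aldex_clr_test(scaled, groups, n_mc=32, seed=7)
        # CLR removes per-sample scale up to the Dirichlet resampling noise
        assert np.abs(t1["effect"] - t2["effect"]).max() < 0.5
        assert np.abs(t1["p_raw"] - t2["p_raw"]).max() < 0.1

    def test_expected_p_stabilizes_with_more_instances(self):
        rng = np.random.default_rng(4)
        counts, groups = count_table(rng, n_per_group=10, n_features=15)
        p64 = differential.aldex_clr_test(counts, groups, n_mc=64, seed=1)["p_raw"]
        p128 = differential.aldex_clr_test(counts, groups, n_mc=128, seed=2)["p_raw"]
        assert np.abs(p64 - p128).max() < 0.05

    def test_small_groups_rejected(self):
        counts, groups = count_table(np.random.default_rng(0), n_per_group=2)
        with pytest.raises(ValueError):
            differential.aldex_clr_test(counts, groups)


class TestVolcano:
    def intensity_table(self, rng, shift_feature=None, lfc=0.0, n_per=15,
                        n_features=30, noise=0.15):
        base = rng.uniform(14, 22, n_features)
        rows, labels = [], []
        for g in range(2):
            eff = np.zeros(n_features)
            if shift_feature is not None and g == 1:
                eff[shift_feature] = lfc
            for _ in range(n_per):
                rows.append(2 ** (base + eff + rng.normal(0, noise, n_features)))
                labels.append("ab"[g])
        ids = [f"s{i}" for i in range(2 * n_per)]
        vals = pd.DataFrame(rows, index=ids,
                            columns=[f"m{j}" for j in range(n_features)])
        return vals, pd.Series(labels, index=ids)

    def test_identical_groups_no_calls(self):
        rng = np.random.default_rng(5)
        vals, groups = self.intensity_table(rng)
        table = differential.volcano_test(vals, groups)
        assert (table["call"] == "ns").all()

    def test_planted_fourfold_shift_called_up(self):
        rng = np.random.default_rng(6)
        vals, groups = self.intensity_table(rng, shift_feature=0, lfc=2.0)
        table = differential.volcano_test(vals, groups)
        assert table.loc["m0", "call"] == "up"
        assert table.loc["m0", "effect"] == pytest.approx(2.0, abs=0.3)

    def test_lfc_exactly_one_is_not_called(self):
        # constant within-group intensities make the fold change exactly 2x
        ids = [f"s{i}" for i in range(12)]
        vals = pd.DataFrame({"m0": [100.0] * 6 + [200.0] * 6,
                             "m1": [100.0] * 6 + [450.0] * 6}, index=ids)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=ids)
        table = differential.volcano_test(vals, groups)
        assert table.loc["m0", "effect"] == pytest.approx(1.0)
        assert table.loc["m0", "call"] == "ns"  # strict "> 1" boundary
        assert table.loc["m1", "call"] == "up"  # LFC ~2.17 with the same p

    def test_downward_shift_called_down(self):
        rng = np.random.default_rng(8)
        vals, groups = self.intensity_table(rng, shift_feature=3, lfc=-2.5)
        table = differential.volcano_test(vals, groups)
        assert table.loc["m3", "call"] == "down"


class TestORA:
    def test_closed_form_hypergeometric(self):
        background = [f"f{i}" for i in range(20)]
        sets = {"s": background[:5]}
        table = differential.ora(background[:5], background, sets)
        assert table.loc["s", "p_raw"] == pytest.approx(1 / comb(20, 5, exact=True))
        assert table.loc["s", "overlap"] == 5

    def test_proportional_overlap_not_significant(self):
        background = [f"f{i}" for i in range(100)]
        sets = {"s": background[:20]}
        hits = background[:2] + background[50:58]  # 2/10 hits in a 20% set
        table = differential.ora(hits, background, sets)
        assert table.loc["s", "p_raw"] > 0.4
        assert not table.loc["s", "significant"]

    def test_hits_equal_background_gives_certainty(self):
        background = [f"f{i}" for i in range(10)]
        table = differential.ora(background, background, {"s": background[:4]})
        assert table.loc["s", "p_raw"] == pytest.approx(1.0)
        assert table.loc["s", "q"] == pytest.approx(1.0)

    def test_empty_hits_returns_empty_table(self):
        table = differential.ora([], ["a", "b"], {"s": ["a"]})
        assert table.empty

    def test_p_invariant_to_feature_renaming(self):
        background = [f"f{i}" for i in range(30)]
        hits = background[:6]
        sets = {"s": background[:8]}
        t1 = differential.ora(hits, background, sets)
        renamed = {f: f"x_{f}" for f in background}
        t2 = differential.ora([renamed[h] for h in hits],
                              list(renamed.values()),
                              {"s": [renamed[f] for f in sets["s"]]})
        assert t1.loc["s", "p_raw"] == pytest.approx(t2.loc["s", "p_raw"])

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError):
            differential.ora(["z"], ["a", "b"], {})


class TestReferenceCluster:
    def test_lowest_burden_wins_with_control_tiebreak(self):
        labels = pd.Series([0] * 10 + [1] * 10 + [2] * 10)
        control = pd.Series([True] * 3 + [False] * 7
                            + [True] * 9 + [False] * 1
                            + [True] * 5 + [False] * 5)
        scores = pd.DataFrame({
            "f1": [2.0] * 10 + [0.0] * 10 + [0.0] * 10,
            "f2": [1.0] * 10 + [0.0] * 10 + [0.0] * 10,
        })
        # clusters 1 and 2 tie on burden; cluster 1 has more controls
        assert differential.choose_reference_cluster(labels, control, scores) == 1
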