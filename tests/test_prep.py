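import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from cohortclust import prep


def frame(rows, columns=None, index=None):
    arr = np.asarray(rows)
    columns = columns or [f"f{j}" for j in range(arr.shape[1])]
    index = index or [f"s{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=index, columns=columns)


class TestTSS:
    def test_row_proportions(self):
        rel = prep.tss_scale(frame([[2, 2, 4]]))
        assert rel.iloc[0].tolist() == [0.25, 0.25, 0.5]

    def test_single_feature_all_ones(self):
        rel = prep.tss_scale(frame([[5], [9]]))
        assert (rel.to_numpy() == 1.0).all()

    def test_idempotent_on_scaled_rows(self):
        rel = prep.tss_scale(frame([[3, 1, 6], [1, 1, 2]]))
        again = prep.tss_scale(rel)
        assert np.allclose(rel.to_numpy(), again.to_numpy(), atol=1e-12)
        assert np.allclose(again.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_row_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            prep.tss_scale(frame([[1, 2], [0, 0]]))


class TestFilterFeatures:
    def build(self, n=100):
        """100 participants; features straddling both filter boundaries."""
        # mean abundances: 0.004% (drop), 0.006% (keep), 1% flagged (drop),
        # plus prevalence features at 9% (drop) and 10% (keep)
        cols = {}
        cols["low_ab"] = np.full(n, 0.00004)
        cols["ok_ab"] = np.full(n, 0.00006)
        cols["flagged"] = np.full(n, 0.01)
        prev9 = np.zeros(n)
        prev9[:9] = 0.01
        cols["prev9"] = prev9
        prev10 = np.zeros(n)
        prev10[:10] = 0.01
        cols["prev10"] = prev10
        cols["bulk"] = 1.0 - sum(cols.values())
        rel = pd.DataFrame(cols)
        flags = pd.Series("ok", index=rel.columns)
        flags["flagged"] = "unassigned"
        return rel, flags

    def test_boundary_keep_drop_pattern(self):
        rel, flags = self.build()
        kept, report = prep.filter_features(rel, flags=flags)
        assert set(kept.columns) == {"ok_ab", "prev10", "bulk"}
        assert report.dropped_low_abundance == ["low_ab"]
        assert report.dropped_low_prevalence == ["prev9"]
        assert report.dropped_flagged == ["flagged"]

    def test_first_failing_rule_claims_feature(self):
        rel, flags = self.build()
        # flagged feature also has low prevalence in this variant
        rel["flagged"] = 0.0
        rel.loc[rel.index[:2], "flagged"] = 0.01
        kept, report = prep.filter_features(rel, flags=flags)
        assert "flagged" in report.dropped_flagged
        assert "flagged" not in report.dropped_low_prevalence

    def test_report_partitions_features(self):
        rel, flags = self.build()
        _, r = prep.filter_features(rel, flags=flags)
        dropped = (len(r.dropped_flagged) + len(r.dropped_low_abundance)
                   + len(r.dropped_low_prevalence))
        assert r.n_features_out + dropped == r.n_features_in

    def test_idempotent_on_filtered_output(self):
        rel, flags = self.build()
        kept, _ = prep.filter_features(rel, flags=flags)
        again, r2 = prep.filter_features(kept, flags=flags)
        assert list(again.columns) == list(kept.columns)
        assert r2.n_features_out == r2.n_features_in

    def test_threshold_bounds_validated(self):
        rel, _ = self.build()
        with pytest.raises(ValueError):
            prep.filter_features(rel, mean_threshold=0.0)


class TestFBRatio:
    def test_ratios(self):
        tbl = pd.DataFrame({"Firmicutes": [0.4, 0.6], "Bacteroidetes": [0.4, 0.2]})
        out = prep.fb_ratio(tbl)
        assert out.tolist() == pytest.approx([1.0, 3.0])

    def test_zero_bacteroidetes_flagged(self):
        tbl = pd.DataFrame({"Firmicutes": [0.4], "Bacteroidetes": [0.0]})
        assert np.isnan(prep.fb_ratio(tbl).iloc[0])
        assert np.isinf(prep.fb_ratio(tbl, zero_policy="inf").iloc[0])

    def test_missing_phylum_column_raises(self):
        with pytest.raises(KeyError):
            prep.fb_ratio(pd.DataFrame({"Firmicutes": [0.4]}))


def exhaustive_rarefied_shannon(counts: np.ndarray, depth: int) -> float:
    """Brute-force expected Shannon H over all without-replacement subsamples."""
    total = counts.sum()
    expected = 0.0
    ranges = [range(min(c, depth) + 1) for c in counts]
    for combo in itertools.product(*ranges):
        if sum(combo) != depth:
            continue
        prob = np.prod([comb(c, k, exact=True) for c, k in zip(counts, combo)])
        prob /= comb(total, depth, exact=True)
        p = np.array([k for k in combo if k > 0]) / depth
        expected += prob * float(-(p * np.log(p)).sum())
    return expected


class TestRarefiedShannon:
    def test_equal_abundance_at_min_depth_is_log_s(self):
        counts = frame([[10, 10, 10, 10]])
        h = prep.rarefied_shannon(counts, n_reps=5, seed=0, depth=40)
        assert h.iloc[0] == pytest.approx(np.log(4), abs=1e-12)

    def test_single_taxon_sample_zero_diversity(self):
        counts = frame([[50, 0, 0]])
        assert prep.rarefied_shannon(counts, n_reps=10, seed=0).iloc[0] == 0.0

    def test_monte_carlo_matches_enumeration_oracle(self):
        row = np.array([4, 3, 3])
        expected = exhaustive_rarefied_shannon(row, 5)
        n_reps = 400
        h = prep.rarefied_shannon(frame([row.tolist()]), n_reps=n_reps, seed=1,
                                  depth=5)
        # MC SE bound: H values live in [0, ln 3]
        se = np.log(3) / 2 / np.sqrt(n_reps)
        assert h.iloc[0] == pytest.approx(expected, abs=3 * se)

    def test_bounded_by_log_observed_richness(self, small_cohort):
        counts = small_cohort.omics_blocks["taxa"].values.iloc[:10]
        h = prep.rarefied_shannon(counts, n_reps=3, seed=0)
        richness = (counts > 0).sum(axis=1)
        assert (h <= np.log(richness) + 1e-9).all()

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            prep.rarefied_shannon(frame([[1.5, 2.0]]))


class TestExpectedRichness:
    def test_full_depth_recovers_observed_richness(self):
        counts = frame([[5, 3, 0, 2]])
        assert prep.expected_richness(counts, 10).iloc[0] == pytest.approx(3.0)

    def test_depth_one_expects_single_taxon(self):
        counts = frame([[5, 3, 2]])
        assert prep.expected_richness(counts, 1).iloc[0] == pytest.approx(1.0)

    def test_matches_monte_carlo_subsampling(self):
        row = np.array([12, 6, 4, 2, 1])
        analytic = prep.expected_richness(frame([row.tolist()]), 10).iloc[0]
        rng = np.random.default_rng(7)
        draws = np.array([
            (rng.multivariate_hypergeometric(row, 10) > 0).sum()
            for _ in range(2000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert analytic == pytest.approx(draws.mean(), abs=3 * se)

    def test_monotone_in_depth(self):
        counts = frame([[12, 6, 4, 2, 1]])
        values = [prep.expected_richness(counts, d).iloc[0] for d in (1, 5, 10, 20)]
        assert np.all(np.diff(values) >= 0)

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            prep.expected_richness(frame([[2, 1]]), 10)


class TestQCRSDFilter:
    def build(self):
        vals = pd.DataFrame({
            "stable": [100, 100, 100, 50, 60],
            "edge30": [70, 100, 130, 50, 60],
            "noisy": [50, 100, 150, 50, 60],
            "dead": [0, 0, 0, 10, 20],
        }, index=["qc1", "qc2", "qc3", "s1", "s2"], dtype=float)
        qc = pd.Series([True, True, True, False, False], index=vals.index)
        return vals, qc

    def test_boundary_is_strictly_greater_than(self):
        vals, qc = self.build()
        kept, report = prep.qc_rsd_filter(vals, qc)
        # sd(70,100,130)=30, mean=100 -> RSD exactly 30.0 -> kept
        assert "edge30" in kept.columns
        assert "noisy" in report.dropped_high_rsd  # RSD 50
        assert "dead" in report.dropped_high_rsd   # zero-mean QC
        assert "stable" in kept.columns

    def test_requires_three_qc_rows(self):
        vals, qc = self.build()
        qc.iloc[0] = False
        with pytest.raises(ValueError):
            prep.qc_rsd_filter(vals, qc)


class TestRunorderNormalize:
    def build(self, drift=None, n=40, qc_every=5):
        rng = np.random.default_rng(3)
        order = pd.Series(np.arange(1, n + 1), index=[f"s{i}" for i in range(n)])
        qc = pd.Series((np.arange(n) % qc_every) == 0, index=order.index)
        base = np.where(qc, 100.0, 100.0 + rng.normal(0, 5, n))
        y = base if drift is None else base * drift(np.arange(n) / (n - 1))
        vals = pd.DataFrame({"m1": y}, index=order.index)
        return vals, order, qc

    def test_identity_under_constant_qc(self):
        vals, order, qc = self.build()
        out = prep.runorder_normalize(vals, order, qc)
        assert np.allclose(out["m1"], vals["m1"], rtol=1e-6)

    def test_linear_drift_reduces_qc_rsd(self):
        vals, order, qc = self.build(drift=lambda t: 1.0 + t)  # 2x across run
        out = prep.runorder_normalize(vals, order, qc)

        def rsd(v):
            return 100 * v.std(ddof=1) / v.mean()

        assert rsd(out.loc[qc, "m1"]) < rsd(vals.loc[qc, "m1"]) / 2

    def test_median_preserved(self):
        vals, order, qc = self.build(drift=lambda t: 1.0 + 0.5 * t)
        out = prep.runorder_normalize(vals, order, qc)
        assert np.median(out["m1"]) == pytest.approx(np.median(vals["m1"]))

    def test_few_qc_points_fall_back_to_median_centering(self):
        vals, order, qc = self.build()
        qc[:] = False
        qc.iloc[[0, 20]] = True
        out = prep.runorder_normalize(vals, order, qc)
        assert out.shape == vals.shape
        assert np.isfinite(out.to_numpy()).all()
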