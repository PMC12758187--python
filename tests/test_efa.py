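import numpy as np
import pandas as pd
import pytest

from cohortclust import efa


def factor_correlation_matrix(loadings: np.ndarray) -> np.ndarray:
    """Population correlation matrix implied by orthogonal-factor loadings."""
    R = loadings @ loadings.T
    np.fill_diagonal(R, 1.0)
    return R


class TestSuitability:
    def test_independent_items_give_null_bartlett(self):
        rng = np.random.default_rng(0)
        items = pd.DataFrame(rng.standard_normal((500, 6)),
                             columns=[f"x{i}" for i in range(6)])
        rep = efa.suitability(items)
        assert rep.bartlett_p > 0.1
        assert rep.bartlett_df == 15
        # statistic near zero: det(R) ~ 1 for independent noise
        assert rep.bartlett_statistic < 30

    def test_structured_items_pass_kmo_gate(self, two_factor_items):
        items, _ = two_factor_items
        rep = efa.suitability(items)
        assert rep.kmo_overall > 0.5
        assert rep.bartlett_p < 1e-10
        assert ((rep.kmo_per_item >= 0) & (rep.kmo_per_item <= 1)).all()

    def test_singular_correlation_names_collinear_items(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        items = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(100)})
        with pytest.raises(ValueError, match="a.*b|collinear"):
            efa.suitability(items)


class TestVelicerMap:
    def test_identity_correlation_returns_zero_factors(self):
        assert efa.velicer_map(np.eye(10)) == 0

    def test_three_orthogonal_factors_recovered(self):
        # 15 items, 5 per factor, loading 0.8 (analytic R, no sampling noise)
        L = np.zeros((15, 3))
        for j in range(3):
            L[5 * j:5 * (j + 1), j] = 0.8
        assert efa.velicer_map(factor_correlation_matrix(L)) == 3

    def test_single_factor_rank_one_structure(self):
        L = np.full((8, 1), 0.9)
        assert efa.velicer_map(factor_correlation_matrix(L)) == 1

    def test_too_few_variables_rejected(self):
        with pytest.raises(ValueError):
            efa.velicer_map(np.eye(2))


class TestExtractAndRotate:
    def test_one_factor_rotation_is_identity(self):
        rng = np.random.default_rng(3)
        f = rng.standard_normal(400)
        items = pd.DataFrame(
            {f"x{i}": 0.8 * f + 0.6 * rng.standard_normal(400) for i in range(6)})
        model = efa.extract_and_rotate(items, 1)
        R, _ = efa._correlation(items)
        A, _ = efa.extract_ml(R, 1)
        assert np.allclose(np.abs(model.loadings.to_numpy().ravel()),
                           np.abs(A.ravel()), atol=1e-8)
        assert model.factor_correlations.shape == (1, 1)

    def test_two_factor_simple_structure_recovered(self, two_factor_items):
        items, _ = two_factor_items
        model = efa.extract_and_rotate(items, 2, n_starts=10)
        L = model.loadings.to_numpy()
        for i, col in enumerate(items.columns):
            gen = 0 if col.startswith("it0") else 1
            dom = np.argmax(np.abs(L[i]))
            # dominant loading on the generating factor, small cross-loading
            assert abs(L[i, dom]) > 0.5
            assert min(np.abs(L[i])) < 0.3
            assert (dom == gen) == (np.argmax(np.abs(L[0])) == 0 if gen == 0 else True)

    def test_rotation_preserves_fitted_correlation(self, two_factor_items):
        items, _ = two_factor_items
        R, _ = efa._correlation(items)
        A, uniq = efa.extract_ml(R, 2)
        unrotated = A @ A.T + np.diag(uniq)
        model = efa.extract_and_rotate(items, 2, n_starts=10)
        assert np.allclose(model.fitted_correlation(), unrotated, atol=1e-6)

    def test_geomin_criterion_not_worse_than_identity_start(self, two_factor_items):
        items, _ = two_factor_items
        R, _ = efa._correlation(items)
        A, _ = efa.extract_ml(R, 2)
        f_identity, _ = efa._geomin_value_grad(A, efa.GEOMIN_EPS)
        _, _, f_best, _ = efa.geomin_rotate(A, n_starts=10)
        assert f_best <= f_identity + 1e-10

    def test_sign_convention_largest_loading_positive(self, two_factor_items):
        items, _ = two_factor_items
        model = efa.extract_and_rotate(items, 2, n_starts=10)
        L = model.loadings.to_numpy()
        for j in range(2):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0


class TestPruneAndRefit:
    def test_threshold_boundary_is_strict(self):
        loadings = pd.DataFrame({"f1": [0.39, 0.41, -0.45]},
                                index=["low", "high", "neg"])
        assert efa.items_below_threshold(loadings, 0.4) == ["low"]

    def test_well_loading_items_skip_refit(self, two_factor_items):
        items, _ = two_factor_items
        model = efa.prune_and_refit(items, 2, threshold=0.4, n_starts=10)
        assert model.dropped_items == []
        assert model.retained_items == list(items.columns)

    def test_pure_noise_items_are_the_ones_dropped(self, two_factor_items):
        items, _ = two_factor_items
        rng = np.random.default_rng(9)
        noisy = items.copy()
        noisy["junk1"] = rng.standard_normal(len(items))
        noisy["junk2"] = rng.standard_normal(len(items))
        model = efa.prune_and_refit(noisy, 2, threshold=0.4, n_starts=10)
        assert sorted(model.dropped_items) == ["junk1", "junk2"]
        assert "junk1" not in model.retained_items


class TestFactorScores:
    def test_mean_zero_and_truth_correlation(self):
        # high-communality items (loading 0.85, 6 per factor) so the
        # attainable score-truth correlation clearly exceeds 0.9
        rng = np.random.default_rng(21)
        n, lam = 400, 0.85
        f = rng.standard_normal((n, 2))
        data = {}
        for j in range(2):
            for i in range(6):
                data[f"it{j}_{i}"] = (lam * f[:, j]
                                      + np.sqrt(1 - lam ** 2)
                                      * rng.standard_normal(n))
        items = pd.DataFrame(data)
        model = efa.prune_and_refit(items, 2, threshold=0.4, n_starts=10)
        scores = efa.factor_scores(model, items)
        assert np.abs(scores.mean()).max() < 1e-8
        cors = np.abs(np.corrcoef(scores.to_numpy().T, f.T)[:2, 2:])
        assert cors.max(axis=1).min() > 0.9
        assert cors.min(axis=1).max() < 0.4

    def test_identical_responses_get_identical_scores(self, two_factor_items):
        items, _ = two_factor_items
        dup = pd.concat([items.iloc[[0]], items.iloc[[0]]], ignore_index=True)
        model = efa.prune_and_refit(items, 2, threshold=0.4, n_starts=10)
        scores = efa.factor_scores(model, dup)
        assert np.allclose(scores.iloc[0], scores.iloc[1])

    def test_participant_at_item_means_scores_zero(self, two_factor_items):
        items, _ = two_factor_items
        model = efa.prune_and_refit(items, 2, threshold=0.4, n_starts=10)
        at_mean = pd.DataFrame([model.item_means], columns=items.columns)
        scores = efa.factor_scores(model, at_mean)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-10)

    def test_excess_missingness_flags_scores(self, two_factor_items):
        items, _ = two_factor_items
        model = efa.prune_and_refit(items, 2, threshold=0.4, n_starts=10)
        row = items.iloc[[0]].copy()
        row.iloc[0, :6] = np.nan  # 6 of 10 missing -> below 50% threshold
        scores = efa.factor_scores(model, row)
        assert scores.isna().all().all()
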