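"""Allometry regression, MANCOVA, permutation tests, LDA and bgPCA."""

import numpy as np
import pytest

from morphokaryo import (
    LandmarkDataset,
    SimulationParams,
    bg_pca,
    gpa_align,
    homogeneity_of_slopes_test,
    lda_crossval,
    mean_shape_permutation_test,
    nested_mancova,
    regress_shape_on_size,
    simulate_dataset,
    size_comparison,
)
from morphokaryo.datatypes import ShapeData

from oracles import mean_shape_enumeration, wilks_oracle


def make_shapes(y, cs, ids=None):
    """Wrap a flat response matrix as ShapeData for the model functions."""
    n, d = y.shape
    assert d % 2 == 0
    return ShapeData(
        ids=ids or [f"s{i}" for i in range(n)],
        aligned=y.reshape(n, d // 2, 2),
        centroid_sizes=np.asarray(cs, float),
        consensus=y.mean(axis=0).reshape(d // 2, 2),
        tangent_projected=True,
    )


class TestAllometryRegression:
    def test_recovers_direction_and_fraction_under_tiny_noise(self, rng):
        n, d = 200, 20
        cs = rng.uniform(80, 120, n)
        beta = rng.standard_normal(d)
        beta /= np.linalg.norm(beta)
        y = np.outer(cs - cs.mean(), beta) * 0.001 + rng.normal(0, 1e-5, (n, d))
        model = regress_shape_on_size(make_shapes(y, cs), n_perm=99, seed=0)
        v = model.allometric_vector / np.linalg.norm(model.allometric_vector)
        assert abs(v @ beta) > 0.99
        assert model.percent_variance > 99.0

    def test_generated_fraction_recovered_at_large_n(self):
        data = simulate_dataset(SimulationParams(
            n_per_race=(400, 120), allometry_fraction=0.05, seed=3))
        shapes = gpa_align(data["landmarks"])
        model = regress_shape_on_size(shapes, n_perm=99, seed=0)
        assert model.percent_variance / 100 == pytest.approx(0.05, abs=0.02)

    def test_residuals_orthogonal_to_size(self, rng):
        n, d = 60, 12
        cs = rng.uniform(1, 2, n)
        y = rng.standard_normal((n, d))
        model = regress_shape_on_size(make_shapes(y, cs), n_perm=99, seed=0)
        sc = cs - cs.mean()
        np.testing.assert_allclose(sc @ model.residuals, 0.0, atol=1e-8)

    def test_type_one_error_near_alpha(self, rng):
        rejections = 0
        reps = 120
        for i in range(reps):
            y = rng.standard_normal((30, 10))
            cs = rng.uniform(1, 2, 30)
            m = regress_shape_on_size(make_shapes(y, cs), n_perm=99, seed=i)
            rejections += m.p_value <= 0.05
        assert 0.01 <= rejections / reps <= 0.11

    def test_zero_size_variance_rejected(self, rng):
        y = rng.standard_normal((10, 6))
        with pytest.raises(ValueError, match="variance"):
            regress_shape_on_size(make_shapes(y, np.ones(10)), n_perm=99)


class TestHomogeneityOfSlopes:
    def test_single_level_rejected(self, rng):
        y = rng.standard_normal((20, 8))
        with pytest.raises(ValueError, match="2 levels"):
            homogeneity_of_slopes_test(y, rng.uniform(1, 2, 20), ["a"] * 20)

    def test_common_slope_rejects_at_alpha(self, rng):
        rejections = 0
        reps = 60
        for i in range(reps):
            n = 40
            cs = rng.uniform(1, 2, n)
            fac = np.repeat(["a", "b"], n // 2)
            beta = rng.standard_normal(8)
            y = np.outer(cs, beta) + rng.standard_normal((n, 8))
            res = homogeneity_of_slopes_test(y, cs, fac, n_perm=99, seed=i)
            rejections += res.p <= 0.05
        assert rejections / reps <= 0.15

    @pytest.mark.parametrize("variant", ["full_factorial", "size_only"])
    def test_detects_group_specific_slopes(self, rng, variant):
        hits = 0
        for i in range(10):
            n = 60
            cs = rng.uniform(1, 2, n)
            fac = np.repeat(["a", "b"], n // 2)
            b1 = np.zeros(8); b1[0] = 3.0
            b2 = np.zeros(8); b2[1] = 3.0
            slope = np.where((fac == "a")[:, None], b1, b2)
            y = slope * cs[:, None] + 0.5 * rng.standard_normal((n, 8))
            res = homogeneity_of_slopes_test(y, cs, fac, n_perm=199, seed=i,
                                             variant=variant)
            hits += res.p <= 0.05
        assert hits >= 8


class TestSizeComparison:
    def test_exact_weight_confound(self, rng):
        weight = rng.uniform(10, 30, 40)
        cs = 2.0 * weight
        race = np.repeat(["ACR", "CD"], 20)
        res = size_comparison(cs, race, weight=weight)
        assert res.p > 0.99
        assert res.extra["weight_p"] < 1e-10

    def test_two_sd_shift_detected(self, rng):
        cs = np.concatenate([rng.normal(100, 5, 20), rng.normal(110, 5, 20)])
        race = np.repeat(["ACR", "CD"], 20)
        assert size_comparison(cs, race).p < 0.01

    def test_identical_distributions_not_significant_typically(self, rng):
        ps = []
        for i in range(40):
            cs = rng.normal(100, 5, 40)
            ps.append(size_comparison(cs, np.repeat(["a", "b"], 20)).p)
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.15


class TestNestedMancova:
    def test_zero_group_effect_gives_lambda_one(self, rng):
        block = rng.standard_normal((6, 4))
        y = np.vstack([block, block])  # identical group blocks -> H == 0
        race = np.repeat(["a", "b"], 6)
        pop = race
        res = nested_mancova(y, race, pop)
        race_term = [r for r in res if r.term == "race"][0]
        assert race_term.statistic == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_computed_wilks_on_8_specimens(self, rng):
        y = rng.standard_normal((8, 2)) + np.repeat([[0, 0], [1.0, 0.5]], 4, axis=0)
        race = np.repeat(["a", "b"], 4)
        res = nested_mancova(y, race, race)
        race_term = [r for r in res if r.term == "race"][0]
        assert race_term.statistic == pytest.approx(wilks_oracle(y, race), abs=1e-10)
        assert race_term.df[0] == 2  # p variables x q hypothesis df

    def test_df_bookkeeping_matches_shape_dimensionality(self, default_sim):
        shapes = gpa_align(default_sim["landmarks"])
        meta = default_sim["metadata"]
        res = nested_mancova(shapes.flat, meta["race"].to_numpy(),
                             meta["population"].to_numpy(), shapes.centroid_sizes)
        terms = {r.term: r for r in res}
        assert terms["race"].df[0] == 26          # (2k-4) x 1
        assert terms["population(race)"].df[0] == 104  # (2k-4) x (6-2)

    def test_race_effect_detected_on_default_data(self, default_sim):
        shapes = gpa_align(default_sim["landmarks"])
        meta = default_sim["metadata"]
        res = nested_mancova(shapes.flat, meta["race"].to_numpy(),
                             meta["population"].to_numpy(), shapes.centroid_sizes)
        race_term = [r for r in res if r.term == "race"][0]
        assert race_term.p < 0.001
        assert 0 < race_term.statistic < 1

    def test_non_nested_design_rejected(self, rng):
        y = rng.standard_normal((12, 4))
        race = np.repeat(["a", "b"], 6)
        pop = np.tile(["p1", "p2"], 6)  # p1 spans both races
        with pytest.raises(ValueError, match="spanning"):
            nested_mancova(y, race, pop)

    def test_invariant_to_orthogonal_rotation_of_responses(self, rng):
        y = rng.standard_normal((24, 6))
        race = np.repeat(["a", "b"], 12)
        pop = np.repeat(["p1", "p2", "p3", "p4"], 6)
        cs = rng.uniform(1, 2, 24)
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        lam1 = [r.statistic for r in nested_mancova(y, race, pop, cs)]
        lam2 = [r.statistic for r in nested_mancova(y @ q, race, pop, cs)]
        np.testing.assert_allclose(lam1, lam2, atol=1e-8)


class TestMeanShapePermutation:
    def test_identical_groups_distance_zero_p_one(self, rng):
        block = rng.standard_normal((5, 6))
        y = np.vstack([block, block])
        res = mean_shape_permutation_test(y, np.repeat(["a", "b"], 5), n_perm=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_exact_enumeration_matches_independent_oracle(self, rng):
        y = rng.standard_normal((10, 6))
        labels = np.repeat(["a", "b"], 5)
        res = mean_shape_permutation_test(y, labels, n_perm=10000, seed=0)
        obs, p = mean_shape_enumeration(y, labels)
        assert res.statistic == pytest.approx(obs, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_null_rejection_near_alpha(self, rng):
        rejections = 0
        reps = 100
        for i in range(reps):
            y = rng.standard_normal((24, 8))
            labels = np.repeat(["a", "b"], 12)
            res = mean_shape_permutation_test(y, labels, n_perm=99, seed=i)
            rejections += res.p <= 0.05
        assert 0.01 <= rejections / reps <= 0.11

    def test_small_group_rejected(self, rng):
        y = rng.standard_normal((5, 4))
        with pytest.raises(ValueError, match="3 specimens"):
            mean_shape_permutation_test(y, ["a", "a", "a", "b", "b"], n_perm=99)


class TestLDACrossval:
    def test_separated_clusters_classified_perfectly(self, rng):
        y = np.vstack([rng.normal(0, 0.1, (20, 6)), rng.normal(5, 0.1, (20, 6))])
        labels = np.repeat(["a", "b"], 20)
        assert lda_crossval(y, labels) == 1.0

    def test_random_labels_near_chance(self, rng):
        rates = []
        for i in range(15):
            y = rng.standard_normal((30, 6))
            labels = np.array(["a", "b"])[rng.integers(0, 2, 30)]
            if len(set(labels)) < 2:
                continue
            rates.append(lda_crossval(y, labels))
        assert 0.3 <= np.mean(rates) <= 0.7

    def test_loo_not_better_than_resubstitution_on_average(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        deltas = []
        for i in range(20):
            y = rng.standard_normal((30, 6))
            y[15:] += 0.5
            labels = np.repeat(["a", "b"], 15)
            loo = lda_crossval(y, labels)
            lda = LinearDiscriminantAnalysis().fit(y, labels)
            resub = float(np.mean(lda.predict(y) == labels))
            deltas.append(resub - loo)
        assert np.mean(deltas) >= 0


class TestBgPCA:
    def test_two_groups_give_one_axis(self, rng):
        y = rng.standard_normal((20, 6))
        out = bg_pca(y, np.repeat(["a", "b"], 10))
        assert out["axes"].shape[1] == 1

    def test_collinear_group_means_second_axis_null(self, rng):
        base = rng.standard_normal(6)
        y = np.vstack([
            rng.normal(0, 0.01, (8, 6)) + t * base for t in (0.0, 1.0, 2.0)
        ])
        out = bg_pca(y, np.repeat(["a", "b", "c"], 8))
        assert out["eigenvalues"][1] < 1e-3 * out["eigenvalues"][0]

    def test_group_mean_projections_match_eigen_oracle(self, rng):
        y = rng.standard_normal((30, 8)) + np.repeat(rng.normal(0, 2, (3, 8)), 10, axis=0)
        groups = np.repeat(["a", "b", "c"], 10)
        out = bg_pca(y, groups)
        means = np.vstack([y[groups == g].mean(axis=0) for g in ("a", "b", "c")])
        mc = means - means.mean(axis=0)
        evals, evecs = np.linalg.eigh(mc.T @ mc / 2)
        order = np.argsort(evals)[::-1][:2]
        oracle_scores = mc @ evecs[:, order]
        # same subspace: scores agree up to per-axis sign
        for j in range(2):
            c = np.corrcoef(out["group_scores"][:, j], oracle_scores[:, j])[0, 1]
            assert abs(c) > 1 - 1e-10

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            bg_pca(rng.standard_normal((10, 4)), ["a"] * 10)
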