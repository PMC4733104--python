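"""Genetic/karyotypic distances, Mantel tests, PCoA and RRPP."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from morphokaryo import (
    DistanceMatrix,
    SimulationParams,
    chord_distance,
    karyotype_distance_matrix,
    mantel,
    nei_da_distance,
    partial_mantel,
    pcoa,
    rrpp_model_compare,
    simulate_dataset,
)
from morphokaryo.datatypes import GenotypeTable
from morphokaryo.linmodels import (
    design_continuous,
    design_factor,
    design_intercept,
)

from oracles import mantel_enumeration


def dm_from_points(points, labels=None):
    points = np.asarray(points, float)
    vals = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    labels = labels or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(labels, vals)


class TestKaryotypeDistance:
    def test_same_zero_different_one(self):
        dm = karyotype_distance_matrix(np.array(["ACR", "ACR", "CD"]))
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == 1.0 and dm.values[1, 2] == 1.0

    def test_all_same_warns_and_is_zero(self):
        with pytest.warns(UserWarning, match="single karyotype"):
            dm = karyotype_distance_matrix(np.array(["x"] * 4))
        assert np.all(dm.values == 0)

    def test_all_distinct_all_ones_off_diagonal(self):
        dm = karyotype_distance_matrix(np.array(["a", "b", "c", "d"]))
        off = dm.values[~np.eye(4, dtype=bool)]
        assert np.all(off == 1.0)


def table(rows, loci=None):
    rows = np.asarray(rows, int)
    ids = [f"i{j}" for j in range(rows.shape[0])]
    loci = loci or [f"L{j}" for j in range(rows.shape[1])]
    return GenotypeTable(ids, loci, rows)


class TestGeneticDistances:
    def test_identical_homozygotes_distance_zero(self):
        g = table([[[1, 1], [2, 2]], [[1, 1], [2, 2]]])
        assert nei_da_distance(g).values[0, 1] == pytest.approx(0.0)
        assert chord_distance(g).values[0, 1] == pytest.approx(0.0)

    def test_fixed_differences_give_maxima(self):
        g = table([[[1, 1], [3, 3]], [[2, 2], [4, 4]]])
        assert nei_da_distance(g).values[0, 1] == pytest.approx(1.0)
        assert chord_distance(g).values[0, 1] == pytest.approx(
            (2 / np.pi) * np.sqrt(2.0)
        )

    def test_het_vs_hom_single_locus(self):
        g = table([[[1, 2]], [[1, 1]]])
        assert nei_da_distance(g).values[0, 1] == pytest.approx(1 - np.sqrt(0.5))

    def test_missing_locus_excluded_pairwise(self):
        g = table([[[1, 1], [0, 0]], [[1, 1], [2, 2]]])
        # locus 2 missing in individual 1: distance from locus 1 only
        assert nei_da_distance(g).values[0, 1] == pytest.approx(0.0)

    def test_no_shared_loci_rejected(self):
        g = table([[[1, 1], [0, 0]], [[0, 0], [2, 2]]])
        with pytest.raises(ValueError, match="share no typed locus"):
            nei_da_distance(g)

    def test_chord_monotone_with_nei(self, rng):
        g = simulate_dataset(SimulationParams(n_per_race=(20, 10), seed=8))["genotypes"]
        da = nei_da_distance(g).condensed()
        ch = chord_distance(g).condensed()
        rho = spearmanr(da, ch).statistic
        assert rho > 0.9


class TestMantel:
    def test_identity_r_one(self, rng):
        a = dm_from_points(rng.normal(size=(8, 2)))
        res = mantel(a, a, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_enumeration_matches_oracle_n5(self, rng):
        a = dm_from_points(rng.normal(size=(5, 2)))
        b = dm_from_points(rng.normal(size=(5, 2)), labels=a.labels)
        res = mantel(a, b, n_perm=10000, seed=0)
        r_oracle, p_oracle = mantel_enumeration(a.values, b.values)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_perm == 120

    def test_agrees_with_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        a = dm_from_points(rng.normal(size=(20, 2)))
        pts = rng.normal(size=(20, 2))
        b = dm_from_points(pts + 0.5 * rng.normal(size=(20, 2)), labels=a.labels)
        res = mantel(a, b, n_perm=999, seed=1)
        r_sk, p_sk, _ = skbio_mantel(SkbioDM(a.values), SkbioDM(b.values),
                                     permutations=999, alternative="greater")
        assert res.r == pytest.approx(float(r_sk), abs=1e-12)
        assert res.p == pytest.approx(float(p_sk), abs=0.05)

    def test_invariant_to_monotone_linear_rescaling(self, rng):
        a = dm_from_points(rng.normal(size=(10, 2)))
        b = dm_from_points(rng.normal(size=(10, 2)), labels=a.labels)
        res1 = mantel(a, b, n_perm=99, seed=2)
        a2 = DistanceMatrix(a.labels, 3.5 * a.values)
        res2 = mantel(a2, b, n_perm=99, seed=2)
        assert res1.r == pytest.approx(res2.r, abs=1e-12)
        assert res1.p == res2.p

    def test_zero_variance_matrix_rejected(self, rng):
        a = DistanceMatrix(list("abcd"), np.ones((4, 4)) - np.eye(4))
        b = dm_from_points(rng.normal(size=(4, 2)), labels=a.labels)
        with pytest.raises(ValueError, match="zero variance"):
            mantel(a, b, n_perm=99)

    def test_alignment_by_labels(self, rng):
        pts = rng.normal(size=(6, 2))
        a = dm_from_points(pts)
        order = list(reversed(a.labels))
        b = a.submatrix(order)
        res = mantel(a, b, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)


class TestPartialMantel:
    def test_b_equals_c_gives_zero(self, rng):
        a = dm_from_points(rng.normal(size=(8, 2)))
        b = dm_from_points(rng.normal(size=(8, 2)), labels=a.labels)
        res = partial_mantel(a, b, b, n_perm=99, seed=0)
        assert res.r == pytest.approx(0.0, abs=1e-10)

    def test_a_equals_b_gives_one(self, rng):
        a = dm_from_points(rng.normal(size=(8, 2)))
        c = dm_from_points(rng.normal(size=(8, 2)), labels=a.labels)
        res = partial_mantel(a, a, c, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_uncorrelated_control_leaves_r_unchanged(self, rng):
        rs, prs = [], []
        for i in range(30):
            pts = rng.normal(size=(25, 2))
            a = dm_from_points(pts)
            b = dm_from_points(pts + rng.normal(size=(25, 2)), labels=a.labels)
            c = dm_from_points(rng.normal(size=(25, 2)), labels=a.labels)
            rs.append(mantel(a, b, n_perm=99, seed=i).r)
            prs.append(partial_mantel(a, b, c, n_perm=99, seed=i).r)
        assert np.mean(np.asarray(rs) - np.asarray(prs)) == pytest.approx(0.0, abs=0.03)

    def test_constant_pattern_control_refused(self, rng):
        a = dm_from_points(rng.normal(size=(5, 2)))
        b = dm_from_points(rng.normal(size=(5, 2)), labels=a.labels)
        c = DistanceMatrix(a.labels, 1.0 - np.eye(5))
        with pytest.raises(ValueError, match="zero variance"):
            partial_mantel(a, b, c, n_perm=99)


class TestPCoA:
    def test_planar_points_recovered_exactly(self, rng):
        pts = rng.normal(size=(4, 2))
        res = pcoa(dm_from_points(pts))
        pos = res.eigenvalues > 1e-10
        assert pos.sum() == 2
        d_rec = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=-1
        )
        d_orig = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.testing.assert_allclose(d_rec, d_orig, atol=1e-9)

    def test_one_dimensional_arrangement_one_axis(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6)])
        res = pcoa(dm_from_points(pts), min_variance_fraction=0.01)
        assert res.retained == 1

    def test_matches_skbio_eigenvalues(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        g = simulate_dataset(SimulationParams(n_per_race=(20, 8), seed=4))["genotypes"]
        d = nei_da_distance(g)
        res = pcoa(d)
        sk = skbio_pcoa(d.values, method="eigh")
        sk_pos = np.sort(sk.eigvals[sk.eigvals > 1e-10])[::-1]
        ours_pos = res.eigenvalues[res.eigenvalues > 1e-10]
        np.testing.assert_allclose(ours_pos, sk_pos[: len(ours_pos)], rtol=1e-8)

    def test_tangent_distance_pcoa_matches_pca_scores(self, rng):
        y = rng.standard_normal((30, 10))
        yc = y - y.mean(axis=0)
        d = DistanceMatrix(
            [f"s{i}" for i in range(30)],
            np.linalg.norm(yc[:, None] - yc[None, :], axis=-1),
        )
        res = pcoa(d, min_variance_fraction=0.0)
        u, s, _ = np.linalg.svd(yc, full_matrices=False)
        scores = u * s
        for j in range(3):
            c = np.corrcoef(res.coordinates[:, j], scores[:, j])[0, 1]
            assert abs(c) > 0.999

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            pcoa(DistanceMatrix(list("abc"), np.zeros((3, 3))))


class TestRRPP:
    @staticmethod
    def designs(n, race, scores):
        from morphokaryo.linmodels import DesignMatrix

        x_g = DesignMatrix(scores, [f"g{i}" for i in range(scores.shape[1])])
        reduced = design_intercept(n).hstack(x_g)
        full = reduced.hstack(design_factor(race, "race"))
        return full, reduced

    def test_observed_f_matches_direct_ss_decomposition(self, rng):
        n = 30
        scores = rng.standard_normal((n, 3))
        race = np.repeat(["a", "b"], 15)
        y = rng.standard_normal((n, 6)) + (race == "b")[:, None]
        full, reduced = self.designs(n, race, scores)
        res = rrpp_model_compare(y, full, reduced, n_perm=99, seed=0)

        def sse(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ beta
            return float(np.sum(r * r))

        sse_f, sse_r = sse(full.x), sse(reduced.x)
        df_f, df_r = 5, 4
        f_oracle = ((sse_r - sse_f) / (df_f - df_r)) / (sse_f / (n - df_f))
        assert res.statistic == pytest.approx(f_oracle, rel=1e-10)

    def test_null_extra_term_rejects_at_alpha(self, rng):
        rejections = 0
        reps = 80
        for i in range(reps):
            n = 30
            scores = rng.standard_normal((n, 3))
            race = np.repeat(["a", "b"], 15)
            y = rng.standard_normal((n, 6))
            full, reduced = self.designs(n, race, scores)
            res = rrpp_model_compare(y, full, reduced, n_perm=99, seed=i)
            rejections += res.p <= 0.05
        assert 0.0 <= rejections / reps <= 0.125

    def test_collinear_predictors_identified(self, rng):
        from morphokaryo.linmodels import DesignMatrix

        n = 20
        x = rng.standard_normal(n)
        cols = np.column_stack([np.ones(n), x, 2 * x])
        full = DesignMatrix(cols, ["intercept", "x", "x_copy"])
        reduced = design_intercept(n)
        with pytest.raises(ValueError, match="x_copy|x"):
            rrpp_model_compare(rng.standard_normal((n, 3)), full, reduced, n_perm=99)

    def test_power_for_real_race_effect(self, rng):
        hits = 0
        for i in range(10):
            n = 60
            scores = rng.standard_normal((n, 3))
            race = np.repeat(["a", "b"], 30)
            y = rng.standard_normal((n, 6)) + 0.8 * (race == "b")[:, None]
            full, reduced = self.designs(n, race, scores)
            hits += rrpp_model_compare(y, full, reduced, n_perm=199, seed=i).p <= 0.05
        assert hits >= 9
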