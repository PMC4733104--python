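"""Generalized Procrustes analysis, centroid size and shape distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphokaryo import (
    DEFAULT_PARTITION,
    LandmarkDataset,
    centroid_size,
    gpa_align,
    pairwise_shape_distances,
    procrustes_distance,
    subset_landmarks,
)
from morphokaryo.gpa import tangent_vs_full_correlation

from conftest import random_shapes
from oracles import full_procrustes_distance_grid, gpa_alternating_oracle


def similarity_transform(coords, angle, scale, shift):
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return coords @ rot.T * scale + shift


class TestCentroidSize:
    def test_unit_square_is_sqrt8(self):
        cfg = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], float)
        assert centroid_size(cfg) == pytest.approx(np.sqrt(8))

    def test_translation_invariance_and_homogeneity(self, rng):
        cfg = rng.normal(size=(7, 2))
        assert centroid_size(cfg + [3.2, -1.7]) == pytest.approx(centroid_size(cfg))
        assert centroid_size(cfg * 3) == pytest.approx(3 * centroid_size(cfg))

    def test_degenerate_configuration_is_zero(self):
        assert centroid_size(np.ones((5, 2))) == 0.0


class TestGPA:
    def test_similarity_copies_align_exactly(self, rng):
        base = random_shapes(rng, 1, 8)[0]
        other = similarity_transform(base, np.pi / 2, 2.0, [5.0, -3.0])
        ds = LandmarkDataset(["a", "b"], np.stack([base, other]))
        shapes = gpa_align(ds)
        np.testing.assert_allclose(shapes.aligned[0], shapes.aligned[1], atol=1e-9)
        assert procrustes_distance(shapes.aligned[0], shapes.aligned[1]) < 1e-9

    def test_identical_shapes_consensus_equals_unit_shape(self, rng):
        base = random_shapes(rng, 1, 10)[0]
        ds = LandmarkDataset([f"s{i}" for i in range(5)], np.stack([base] * 5))
        shapes = gpa_align(ds)
        unit = base - base.mean(axis=0)
        unit /= np.linalg.norm(unit)
        assert procrustes_distance(shapes.consensus, unit) < 1e-9

    def test_invariance_to_pre_applied_similarity_maps(self, rng):
        coords = random_shapes(rng, 12, 15)
        ds = LandmarkDataset([f"s{i}" for i in range(12)], coords)
        ref = gpa_align(ds)
        transformed = np.stack([
            similarity_transform(c, rng.uniform(0, 2 * np.pi),
                                 rng.uniform(0.2, 5.0), rng.uniform(-9, 9, 2))
            for c in coords
        ])
        out = gpa_align(LandmarkDataset(ds.ids, transformed))
        np.testing.assert_allclose(out.aligned, ref.aligned, atol=1e-9)

    def test_consensus_matches_alternating_optimization_oracle(self, rng):
        coords = random_shapes(rng, 10, 8)
        shapes = gpa_align(LandmarkDataset([f"s{i}" for i in range(10)], coords),
                           project_tangent=False)
        oracle = gpa_alternating_oracle(coords, n_restarts=3, seed=0)
        assert procrustes_distance(shapes.consensus, oracle, mode="full") < 1e-6

    def test_consensus_has_unit_size_and_centred_configurations(self, default_sim):
        shapes = gpa_align(default_sim["landmarks"])
        assert np.linalg.norm(shapes.consensus) == pytest.approx(1.0, abs=1e-10)
        centroids = shapes.aligned.mean(axis=1)
        assert np.max(np.abs(centroids)) < 1e-10

    def test_tangent_coordinate_sum_equals_n_times_consensus(self, default_sim):
        shapes = gpa_align(default_sim["landmarks"])
        total = shapes.flat.sum(axis=0)
        np.testing.assert_allclose(total, shapes.n * shapes.consensus.ravel(),
                                   atol=1e-8)

    def test_shape_space_rank_at_most_2k_minus_4(self, default_sim):
        shapes = gpa_align(default_sim["landmarks"])
        yc = shapes.flat - shapes.flat.mean(axis=0)
        rank = np.linalg.matrix_rank(yc, tol=1e-9 * np.linalg.norm(yc))
        assert rank <= 2 * shapes.k - 4

    def test_tangent_distances_track_full_distances(self, default_sim):
        shapes = gpa_align(default_sim["landmarks"])
        assert tangent_vs_full_correlation(shapes) > 0.99

    def test_degenerate_configuration_rejected(self):
        coords = np.stack([np.ones((4, 2)), np.eye(4, 2)[:4].reshape(4, 2)])
        coords[1] = [[0, 0], [1, 0], [0, 1], [1, 1]]
        with pytest.raises(ValueError, match="degenerate"):
            gpa_align(LandmarkDataset(["a", "b"], coords))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(angle=st.floats(0, 2 * np.pi), scale=st.floats(0.1, 10),
           dx=st.floats(-100, 100), dy=st.floats(-100, 100))
    def test_property_alignment_invariant_to_one_transformed_specimen(
        self, angle, scale, dx, dy
    ):
        rng = np.random.default_rng(99)
        coords = random_shapes(rng, 6, 7)
        ds = LandmarkDataset([f"s{i}" for i in range(6)], coords)
        ref = gpa_align(ds)
        coords2 = coords.copy()
        coords2[2] = similarity_transform(coords[2], angle, scale, [dx, dy])
        out = gpa_align(LandmarkDataset(ds.ids, coords2))
        np.testing.assert_allclose(out.aligned, ref.aligned, atol=1e-8)


class TestProcrustesDistance:
    def test_self_and_rotated_copy_are_zero(self, rng):
        a = random_shapes(rng, 1, 6)[0]
        assert procrustes_distance(a, a) == 0.0
        b = similarity_transform(a, 1.1, 3.0, [0.5, 0.5])
        assert procrustes_distance(a, b, mode="full") < 1e-9

    def test_toy_triangles_match_grid_search_oracle(self):
        a = np.array([[0, 0], [1, 0], [0, 1]], float)
        b = np.array([[0, 0], [1, 0], [1, 1]], float)
        oracle = full_procrustes_distance_grid(a, b, resolution=1e-4)
        assert procrustes_distance(a, b, mode="full") == pytest.approx(oracle, abs=1e-4)

    def test_landmark_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            procrustes_distance(rng.normal(size=(5, 2)), rng.normal(size=(6, 2)))


class TestPairwiseDistances:
    def test_identical_shapes_zero_matrix(self, rng):
        base = random_shapes(rng, 1, 6)[0]
        ds = LandmarkDataset(list("abc"), np.stack([base] * 3))
        shapes = gpa_align(ds)
        dm = pairwise_shape_distances(shapes)
        np.testing.assert_allclose(dm.values, 0.0, atol=1e-9)

    def test_triangle_inequality_on_random_shapes(self, rng):
        coords = random_shapes(rng, 50, 7)
        shapes = gpa_align(LandmarkDataset([f"s{i}" for i in range(50)], coords))
        d = pairwise_shape_distances(shapes).values
        lhs = d[:, :, None]
        rhs = d[:, None, :] + d[None, :, :]
        assert np.all(lhs <= rhs + 1e-12)

    def test_matches_elementwise_recomputation(self, rng):
        coords = random_shapes(rng, 5, 6)
        shapes = gpa_align(LandmarkDataset([f"s{i}" for i in range(5)], coords))
        dm = pairwise_shape_distances(shapes)
        for i in range(5):
            for j in range(5):
                d = procrustes_distance(shapes.aligned[i], shapes.aligned[j],
                                        mode="tangent")
                assert dm.values[i, j] == pytest.approx(d, abs=1e-12)


class TestSubsetLandmarks:
    def test_block_dimensions(self, default_sim):
        ds = default_sim["landmarks"]
        sub = subset_landmarks(ds, DEFAULT_PARTITION, "alveolar")
        assert sub.coords.shape == (len(ds), 7, 2)
        sub = subset_landmarks(ds, DEFAULT_PARTITION, "ramus")
        assert sub.coords.shape == (len(ds), 8, 2)

    def test_no_realign_is_bit_exact(self, default_sim):
        shapes = gpa_align(default_sim["landmarks"])
        block = subset_landmarks(shapes, DEFAULT_PARTITION, "ramus", realign=False)
        np.testing.assert_array_equal(
            block, shapes.aligned[:, list(DEFAULT_PARTITION.block_b), :]
        )

    def test_realigned_rotation_only_difference_is_zero(self, rng):
        base = random_shapes(rng, 1, 15)[0]
        other = base.copy()
        idx = list(DEFAULT_PARTITION.block_a)
        other[idx] = similarity_transform(base[idx], 0.7, 1.0, [0, 0])
        ds = LandmarkDataset(["a", "b"], np.stack([base, other]))
        sub = subset_landmarks(ds, DEFAULT_PARTITION, "alveolar", realign=True)
        assert procrustes_distance(sub.aligned[0], sub.aligned[1], "full") < 1e-9
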