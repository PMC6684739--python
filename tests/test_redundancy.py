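"""Lesion distances, redundancy counts, and the high/low median split."""

import numpy as np
import pytest

from lesion2score import generate_lesion
from lesion2score.exceptions import DegeneracyError, GridError
from lesion2score.imaging import GRID_SHAPE, LesionImage
from lesion2score.redundancy import (
    DistanceMatrix,
    centroid_distance,
    centroid_of,
    distance_matrix,
    raw_distance,
    redundancy_counts,
    split_groups,
    topological_distance,
)


def mask_with(coords):
    arr = np.zeros(GRID_SHAPE, dtype=np.uint8)
    for c in coords:
        arr[c] = 1
    return LesionImage(arr)


def translate(image, offset):
    rolled = np.roll(image.voxels, offset, axis=(0, 1, 2))
    return LesionImage(rolled)


class TestCentroid:
    def test_single_voxel(self):
        assert np.allclose(centroid_of(mask_with([(3, 4, 5)])), (3, 4, 5))

    def test_midpoint_of_two_voxels(self):
        assert np.allclose(centroid_of(mask_with([(0, 0, 0), (2, 0, 0)])), (1, 0, 0))

    def test_translation_shifts_centroid_exactly(self):
        im = generate_lesion(1, (20, 30, 20), 120)
        shifted = translate(im, (3, -2, 5))
        assert np.allclose(centroid_of(shifted), centroid_of(im) + [3, -2, 5])

    def test_empty_mask_degenerate(self):
        with pytest.raises(DegeneracyError):
            centroid_of(np.zeros(GRID_SHAPE))

    def test_345_triangle(self):
        a, b = mask_with([(0, 0, 0)]), mask_with([(3, 4, 0)])
        assert centroid_distance(a, b) == pytest.approx(5.0)

    def test_identical_masks_and_symmetry(self):
        a = generate_lesion(2, (25, 30, 25), 60)
        b = generate_lesion(3, (40, 50, 40), 90)
        assert centroid_distance(a, a) == 0.0
        assert centroid_distance(a, b) == pytest.approx(centroid_distance(b, a))


class TestTopologicalDistance:
    def test_integer_translation_gives_zero(self):
        im = generate_lesion(4, (20, 30, 20), 200)
        assert topological_distance(im, translate(im, (4, -3, 2))) == 0.0

    def test_disjoint_after_centering(self):
        # Two shapes that share a centroid cell but no voxels after centring:
        # a 1-voxel mask and a symmetric 2-voxel mask around the same centre.
        a = mask_with([(30, 30, 30)])
        b = mask_with([(29, 30, 30), (31, 30, 30)])
        # crop = bounding box of b (3 voxels along axis 0); disagreement = 1+2
        assert topological_distance(a, b) == pytest.approx(np.sqrt(3))

    def test_symmetric(self):
        a = generate_lesion(5, (20, 30, 20), 150)
        b = generate_lesion(6, (40, 40, 40), 400)
        assert topological_distance(a, b) == pytest.approx(
            topological_distance(b, a), abs=1e-10
        )

    def test_location_insensitive_unlike_raw(self):
        im = generate_lesion(7, (20, 30, 20), 100)
        moved = translate(im, (10, 0, 0))
        assert topological_distance(im, moved) == 0.0
        assert raw_distance(im, moved) > 0.0


class TestRawDistance:
    def test_identical_zero(self):
        im = generate_lesion(8, (30, 30, 30), 50)
        assert raw_distance(im, im) == 0.0

    def test_disjoint_binary_masks(self):
        a = mask_with([(1, 1, 1), (1, 1, 2), (1, 2, 1)])
        b = mask_with([(50, 50, 50), (50, 50, 51)])
        assert raw_distance(a, b) == pytest.approx(np.sqrt(5))

    def test_shape_mismatch_rejected(self):
        im = generate_lesion(9, (30, 30, 30), 10)
        with pytest.raises(GridError):
            raw_distance(im, np.zeros((5, 5, 5)))


class TestDistanceMatrix:
    def test_identical_pair_is_zero_matrix(self):
        im = generate_lesion(10, (30, 30, 30), 40)
        D = distance_matrix([im, im], "raw")
        assert np.allclose(D.values, 0.0)

    @pytest.mark.parametrize("metric", ["centroid", "topological", "raw"])
    def test_matches_nested_loop_reference(self, metric, assorted_lesions):
        """Vectorized/batched matrix equals the brute-force pairwise loop."""
        fn = {"centroid": centroid_distance, "topological": topological_distance,
              "raw": raw_distance}[metric]
        D = distance_matrix(assorted_lesions, metric)
        n = len(assorted_lesions)
        for i in range(n):
            for j in range(n):
                expected = 0.0 if i == j else fn(assorted_lesions[i], assorted_lesions[j])
                assert D.values[i, j] == pytest.approx(expected, abs=1e-6)

    def test_permutation_consistency(self, assorted_lesions):
        D = distance_matrix(assorted_lesions, "centroid").values
        perm = [2, 0, 4, 1, 3]
        Dp = distance_matrix([assorted_lesions[i] for i in perm], "centroid").values
        assert np.allclose(Dp, D[np.ix_(perm, perm)], atol=1e-10)

    @pytest.mark.parametrize("metric", ["centroid", "topological", "raw"])
    def test_pseudometric_properties(self, metric, assorted_lesions):
        D = distance_matrix(assorted_lesions, metric)
        v = D.values
        assert (v >= 0).all()
        assert np.allclose(v, v.T, atol=1e-10)
        assert np.allclose(np.diag(v), 0.0)

    def test_raw_triangle_inequality(self, assorted_lesions):
        v = distance_matrix(assorted_lesions, "raw").values
        n = len(v)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-9

    def test_csv_roundtrip(self, tmp_path, assorted_lesions):
        D = distance_matrix(assorted_lesions, "raw")
        D.to_csv(tmp_path / "d.csv")
        back = DistanceMatrix.from_csv(tmp_path / "d.csv", "raw")
        assert np.allclose(back.values, D.values, atol=1e-9)


class TestRedundancyCounts:
    def test_worked_arithmetic_example(self):
        """Off-diagonal row {0.1, 5,5,5,5,5}: mean 4.1833, population SD
        1.826, threshold 2.357 -> exactly one value below."""
        n = 7
        vals = np.zeros((n, n))
        row = [0.1, 5, 5, 5, 5, 5]
        vals[0, 1:] = row
        vals[1:, 0] = row
        # fill the rest symmetrically with a neutral constant
        for i in range(1, n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = 3.0
        rc = redundancy_counts(DistanceMatrix(vals, "raw"))
        assert rc.thresholds[0] == pytest.approx(4.1833 - 1.8262, abs=1e-3)
        assert rc.counts[0] == 1

    def test_equal_rows_count_zero(self):
        vals = np.full((5, 5), 2.0)
        np.fill_diagonal(vals, 0.0)
        rc = redundancy_counts(DistanceMatrix(vals, "raw"))
        assert (rc.counts == 0).all()
        assert np.allclose(rc.thresholds, 2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(1, 10, size=(6, 6))
        vals = (A + A.T) / 2
        np.fill_diagonal(vals, 0.0)
        rc1 = redundancy_counts(DistanceMatrix(vals, "raw"))
        rc2 = redundancy_counts(DistanceMatrix(vals * 7.3, "raw"))
        assert (rc1.counts == rc2.counts).all()

    def test_too_small_rejected(self):
        with pytest.raises(DegeneracyError):
            redundancy_counts(DistanceMatrix(np.zeros((2, 2)), "raw"))


class TestSplitGroups:
    def _scores(self, counts):
        from lesion2score.redundancy import RedundancyScore

        return RedundancyScore(np.array(counts), np.zeros(len(counts)), "raw")

    def test_median_split(self):
        labels = split_groups(self._scores([0, 0, 5, 5]))
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_go_high(self):
        labels = split_groups(self._scores([1, 2, 3]))
        assert list(labels) == ["low", "high", "high"]

    def test_partition_sums_to_n(self):
        labels = split_groups(self._scores([0, 1, 4, 4, 7]))
        assert (labels == "high").sum() + (labels == "low").sum() == 5

    def test_identical_counts_degenerate(self):
        with pytest.raises(DegeneracyError):
            split_groups(self._scores([3, 3, 3]))

    def test_empty_group_degenerate(self):
        with pytest.raises(DegeneracyError):
            split_groups(self._scores([0, 0, 0, 1]))


class TestClusteredCohortCounts:
    @pytest.mark.parametrize("metric", ["centroid", "topological", "raw"])
    def test_cluster_members_outrank_singletons(self, metric, clustered_cohort):
        """Members of tight clusters must be counted as more redundant than
        the unique singleton lesions, under every distance definition."""
        images, _, member = clustered_cohort
        rc = redundancy_counts(distance_matrix(images, metric))
        assert rc.counts[member].min() > rc.counts[~member].max()
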