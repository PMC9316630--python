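import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_interval_matrix
from hcid import (
    DistanceMatrix,
    IntervalMatrix,
    euclidean_distance_matrix,
    or_distance_matrix,
    overlap_ratio,
    pair_distance,
    pair_similarity,
)

ATOL = 1e-12


def naive_overlap_ratio(a, b):
    """Straight transcription of the definition, scalar arithmetic only."""
    lo_a, hi_a = a
    lo_b, hi_b = b
    inter = max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
    width = hi_a - lo_a
    if width > 0:
        return inter / width
    return 1.0 if lo_b <= lo_a <= hi_b else 0.0


def naive_or_distance(m: IntervalMatrix):
    """Nested-loop evaluation of the J-dimensional OR distance."""
    lo, hi = m.lower, m.upper
    n, j = m.shape
    d = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            total = 0.0
            for f in range(j):
                total += 1.0 - naive_overlap_ratio(
                    (lo[i, f], hi[i, f]), (lo[k, f], hi[k, f])
                )
                total += 1.0 - naive_overlap_ratio(
                    (lo[k, f], hi[k, f]), (lo[i, f], hi[i, f])
                )
            d[i, k] = total / (2 * j)
    return d


class TestOverlapRatio:
    def test_identical_intervals(self):
        assert overlap_ratio((2, 5), (2, 5)) == 1.0

    def test_disjoint_intervals(self):
        assert overlap_ratio((0, 1), (5, 6)) == 0.0

    def test_partial_overlap(self):
        assert overlap_ratio((0, 2), (1, 3)) == pytest.approx(0.5, abs=ATOL)

    def test_asymmetry(self):
        assert overlap_ratio((0, 4), (1, 2)) == pytest.approx(0.25, abs=ATOL)
        assert overlap_ratio((1, 2), (0, 4)) == 1.0

    def test_touching_intervals_do_not_overlap(self):
        assert overlap_ratio((0, 1), (1, 2)) == 0.0
        assert overlap_ratio((1, 2), (0, 1)) == 0.0

    def test_degenerate_rules(self):
        # point inside a closed interval (including its boundary)
        assert overlap_ratio((3, 3), (2, 5)) == 1.0
        assert overlap_ratio((2, 2), (2, 5)) == 1.0
        assert overlap_ratio((6, 6), (2, 5)) == 0.0
        # a positive-width interval is never covered by a point
        assert overlap_ratio((2, 5), (3, 3)) == 0.0
        # two points agree iff equal
        assert overlap_ratio((4, 4), (4, 4)) == 1.0
        assert overlap_ratio((4, 4), (5, 5)) == 0.0

    @given(
        st.floats(-50, 50), st.floats(0, 20), st.floats(-50, 50), st.floats(0, 20)
    )
    @settings(max_examples=200, deadline=None)
    def test_range_and_oracle_agreement(self, lo1, w1, lo2, w2):
        a, b = (lo1, lo1 + w1), (lo2, lo2 + w2)
        v = overlap_ratio(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(naive_overlap_ratio(a, b), abs=ATOL)


class TestPairMeasures:
    def test_hand_evaluated_single_feature(self):
        # intervals [0,2] and [1,3]: both directions give OR = 0.5
        assert pair_distance([1], [1], [2], [1]) == pytest.approx(0.5, abs=ATOL)

    def test_hand_evaluated_two_features(self):
        # feature 1 as above, feature 2 identical pairs
        d = pair_distance([1, 7], [1, 2], [2, 7], [1, 2])
        assert d == pytest.approx(0.25, abs=ATOL)

    def test_identity_rows(self, rng):
        m = random_interval_matrix(rng, 1, 5)
        c, r = m.centers[0], m.radii[0]
        assert pair_distance(c, r, c, r) == 0.0
        assert pair_similarity(c, r, c, r) == 1.0

    def test_fully_disjoint_rows(self):
        assert pair_similarity([0, 0], [1, 1], [100, 100], [1, 1]) == 0.0

    def test_similarity_distance_sum_to_one(self, rng):
        for _ in range(25):
            x = random_interval_matrix(rng, 2, 4, degenerate_frac=0.2)
            s = pair_similarity(x.centers[0], x.radii[0], x.centers[1], x.radii[1])
            d = pair_distance(x.centers[0], x.radii[0], x.centers[1], x.radii[1])
            assert s + d == pytest.approx(1.0, abs=ATOL)

    def test_empty_rows_error(self):
        with pytest.raises(ValueError):
            pair_distance([], [], [], [])


class TestOrDistanceMatrix:
    def test_two_identical_rows(self):
        m = IntervalMatrix([[1.0], [1.0]], [[0.5], [0.5]])
        assert np.array_equal(or_distance_matrix(m).values, np.zeros((2, 2)))

    def test_three_row_toy_matches_hand_values(self):
        m = IntervalMatrix([[1.0], [2.0], [10.0]], [[1.0], [1.0], [1.0]])
        d = or_distance_matrix(m).values
        # [0,2] vs [1,3]: 0.5 each way; [0,2] or [1,3] vs [9,11]: disjoint
        expected = np.array([[0.0, 0.5, 1.0], [0.5, 0.0, 1.0], [1.0, 1.0, 0.0]])
        assert np.allclose(d, expected, atol=ATOL)

    @pytest.mark.parametrize("degenerate_frac", [0.0, 0.3])
    def test_vectorized_equals_nested_loop_oracle(self, rng, degenerate_frac):
        m = random_interval_matrix(rng, 20, 4, degenerate_frac=degenerate_frac)
        assert np.allclose(or_distance_matrix(m).values, naive_or_distance(m), atol=ATOL)

    def test_symmetry_zero_diagonal_and_range(self, rng):
        m = random_interval_matrix(rng, 30, 3, degenerate_frac=0.1)
        d = or_distance_matrix(m)
        v = d.values
        assert np.array_equal(v, v.T)
        assert np.array_equal(np.diag(v), np.zeros(30))
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_affine_invariance_per_feature(self, rng):
        """Replacing feature j by a*x+b (a>0) leaves every distance unchanged."""
        m = random_interval_matrix(rng, 15, 3)
        d0 = or_distance_matrix(m).values
        a = np.array([2.5, 0.1, 7.0])
        b = np.array([-3.0, 40.0, 0.0])
        m2 = IntervalMatrix(m.centers * a + b, m.radii * a)
        assert np.allclose(or_distance_matrix(m2).values, d0, atol=1e-10)

    def test_single_observation_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            or_distance_matrix(IntervalMatrix([[1.0]], [[1.0]]))


class TestEuclideanBaseline:
    def test_three_four_five(self):
        d = euclidean_distance_matrix([[0.0, 0.0], [3.0, 4.0]])
        assert d.values[0, 1] == pytest.approx(5.0, abs=ATOL)
        assert d.metric_tag == "euclidean"

    def test_identical_rows(self):
        d = euclidean_distance_matrix([[1.0, 2.0], [1.0, 2.0]])
        assert d.values[0, 1] == 0.0

    def test_scaling_changes_distances(self, rng):
        x = rng.normal(size=(10, 2)) * np.array([1.0, 100.0])
        d_raw = euclidean_distance_matrix(x).values
        d_scaled = euclidean_distance_matrix(x, scale=True).values
        assert not np.allclose(d_raw, d_scaled)

    def test_zero_variance_feature_with_scale_errors(self):
        x = np.column_stack([np.arange(4.0), np.ones(4)])
        with pytest.raises(ValueError, match="f2"):
            euclidean_distance_matrix(x, scale=True)


class TestDistanceMatrixContainer:
    def test_asymmetric_input_rejected(self):
        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(v, metric_tag="generic")

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(np.eye(3), metric_tag="generic")

    def test_or_entries_bounded(self):
        v = np.array([[0.0, 1.5], [1.5, 0.0]])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            DistanceMatrix(v, metric_tag="or_distance")
        DistanceMatrix(v, metric_tag="generic")  # fine for other metrics

    def test_csv_round_trip(self, tmp_path, rng):
        m = random_interval_matrix(rng, 6, 2)
        d = or_distance_matrix(m)
        p = tmp_path / "d.csv"
        d.to_csv(p)
        back = DistanceMatrix.from_csv(p)
        assert np.allclose(back.values, d.values, atol=1e-12)
        assert back.obs_ids == d.obs_ids

    def test_phylip_export_shape(self, tmp_path, rng):
        m = random_interval_matrix(rng, 5, 2)
        p = tmp_path / "d.phy"
        or_distance_matrix(m).to_phylip(p)
        lines = p.read_text().splitlines()
        assert lines[0].strip() == "5"
        assert len(lines) == 6
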