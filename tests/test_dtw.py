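"""DTW core: pointwise distances, cumulative DP, backtracking, mDTW."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitdtw import (
    backtrack,
    cumulative_matrix,
    distance_matrix,
    dtw,
    dtw_distance_only,
    mdtw_distance,
)
from gaitdtw.errors import ParameterError
from oracles import brute_force_dtw

seqs = st.lists(st.integers(0, 2), min_size=1, max_size=5).map(
    lambda v: np.array(v, dtype=float)
)


class TestDistanceMatrix:
    def test_scalar_abs_difference(self):
        D = distance_matrix(np.array([1.0, 2.0]), np.array([1.0, 3.0]))
        assert D.tolist() == [[0.0, 2.0], [1.0, 1.0]]

    def test_identical_sequences_zero_diagonal(self):
        x = np.array([0.3, -1.2, 4.0])
        assert np.allclose(np.diag(distance_matrix(x, x)), 0.0)

    def test_two_channel_euclidean(self):
        x = np.array([[0.0], [0.0]])
        y = np.array([[3.0], [4.0]])
        assert distance_matrix(x, y)[0, 0] == pytest.approx(5.0)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            distance_matrix(np.zeros((2, 3)), np.zeros((3, 3)))

    def test_nan_rejected(self):
        with pytest.raises(ParameterError):
            distance_matrix(np.array([np.nan, 1.0]), np.array([1.0]))


class TestCumulativeMatrix:
    def test_hand_case_all_ones(self):
        C = cumulative_matrix(np.ones((2, 2)))
        assert C.tolist() == [[1.0, 2.0], [2.0, 2.0]]

    def test_zeros_propagate(self):
        assert np.all(cumulative_matrix(np.zeros((4, 3))) == 0.0)

    def test_single_row_is_prefix_sum(self):
        D = np.array([[1.0, 2.0, 3.0, 4.0]])
        assert cumulative_matrix(D).tolist() == [[1.0, 3.0, 6.0, 10.0]]

    def test_negative_distances_rejected(self):
        with pytest.raises(ParameterError):
            cumulative_matrix(np.array([[1.0, -0.1]]))

    def test_cumulative_dominates_pointwise(self):
        rng = np.random.default_rng(0)
        D = rng.uniform(0, 1, (6, 7))
        assert np.all(cumulative_matrix(D) >= D - 1e-12)


class TestBacktrack:
    def test_identical_sequences_follow_diagonal(self):
        x = np.array([1.0, 5.0, 2.0, 7.0])
        r = dtw(x, x)
        assert r.path == [(i, i) for i in range(4)]

    def test_single_row_forced_horizontal(self):
        C = cumulative_matrix(np.array([[1.0, 1.0, 1.0]]))
        assert backtrack(C) == [(0, 0), (0, 1), (0, 2)]

    def test_tie_prefers_diagonal(self):
        # uniform costs: every predecessor ties, the diagonal must win
        C = cumulative_matrix(np.zeros((3, 3)))
        assert backtrack(C) == [(0, 0), (1, 1), (2, 2)]

    def test_path_endpoints_and_steps(self):
        rng = np.random.default_rng(1)
        r = dtw(rng.normal(size=6), rng.normal(size=9))
        assert r.path[0] == (0, 0) and r.path[-1] == (5, 8)
        steps = {(b[0] - a[0], b[1] - a[1]) for a, b in zip(r.path, r.path[1:])}
        assert steps <= {(1, 0), (0, 1), (1, 1)}

    def test_cost_nondecreasing_along_path(self):
        rng = np.random.default_rng(2)
        r = dtw(rng.normal(size=7), rng.normal(size=5))
        costs = [r.cumulative[i, j] for i, j in r.path]
        assert all(b >= a - 1e-12 for a, b in zip(costs, costs[1:]))


class TestMdtw:
    def test_hand_case_distance_one(self):
        # brute-force enumeration gives 1: 1 warps to the 2-run, 3 to the 3-run
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0, 3.0, 3.0])
        assert brute_force_dtw(x, y) == pytest.approx(1.0)
        assert mdtw_distance(x, y).distance == pytest.approx(1.0)

    @pytest.mark.parametrize("strategy", ["dependent", "independent"])
    def test_single_channel_reduces_to_scalar_dtw(self, strategy):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(1, 10)), rng.normal(size=(1, 14))
        scalar = dtw(x[0], y[0]).distance
        assert mdtw_distance(x, y, strategy).distance == pytest.approx(scalar)
        assert dtw_distance_only(x, y, strategy) == pytest.approx(scalar)

    def test_identity_any_dimension(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(3, 12))
        for strategy in ("dependent", "independent"):
            assert mdtw_distance(x, x, strategy).distance == pytest.approx(0.0)

    def test_dependent_invariant_to_channel_permutation(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(4, 9)), rng.normal(size=(4, 11))
        perm = [2, 0, 3, 1]
        d1 = mdtw_distance(x, y).distance
        d2 = mdtw_distance(x[perm], y[perm]).distance
        assert d1 == pytest.approx(d2)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ParameterError):
            mdtw_distance(np.zeros((1, 3)), np.zeros((1, 3)), "derivative")

    def test_fast_path_matches_full_dp(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.normal(size=(2, rng.integers(4, 30)))
            y = rng.normal(size=(2, rng.integers(4, 30)))
            assert dtw_distance_only(x, y) == pytest.approx(mdtw_distance(x, y).distance)


class TestProperties:
    @given(x=seqs, y=seqs)
    @settings(max_examples=200)
    def test_matches_brute_force_oracle(self, x, y):
        assert dtw(x, y).distance == pytest.approx(brute_force_dtw(x, y))

    @given(x=seqs, y=seqs)
    @settings(max_examples=100)
    def test_symmetry(self, x, y):
        assert dtw(x, y).distance == pytest.approx(dtw(y, x).distance)

    @given(x=seqs, y=seqs)
    @settings(max_examples=100)
    def test_zero_distance_iff_aligned_pairs_equal(self, x, y):
        r = dtw(x, y)
        aligned_equal = all(x[i] == y[j] for i, j in r.path)
        assert (r.distance == 0.0) == aligned_equal

    @given(x=seqs, y=seqs)
    @settings(max_examples=100)
    def test_distance_at_least_endpoint_cost(self, x, y):
        # the (m-1, n-1) cell lies on every admissible path
        assert dtw(x, y).distance >= abs(x[-1] - y[-1]) - 1e-12

    @given(x=seqs, y=seqs, a=st.integers(0, 2))
    @settings(max_examples=100)
    def test_appending_identical_pair_never_increases(self, x, y, a):
        base = dtw(x, y).distance
        ext = dtw(np.append(x, a), np.append(y, a)).distance
        assert ext <= base + 1e-12
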