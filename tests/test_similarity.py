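import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssematch import (
    bd_score,
    build_feature_graph,
    build_similarity_matrix,
    comparable_rows,
    mac_score,
)
from conftest import random_vector_set

positive_rows = st.lists(
    st.floats(min_value=0.01, max_value=100.0, allow_nan=False), min_size=2, max_size=8
)


class TestComparableRows:
    def test_sort_and_pad_shorter_row(self):
        a, c = comparable_rows([3, 1, 2], [2, 5])
        assert a.tolist() == [3, 2, 1]
        assert c.tolist() == [5, 2, 0]

    def test_equal_length_rows_only_sorted(self):
        a, c = comparable_rows([1, 4], [7, 2])
        assert a.tolist() == [4, 1] and c.tolist() == [7, 2]

    def test_pad_much_shorter(self):
        a, c = comparable_rows([1], [4, 4, 4])
        assert a.tolist() == [1, 0, 0] and c.tolist() == [4, 4, 4]

    def test_truncate_mode_cuts_longer_row(self):
        a, c = comparable_rows([3, 1, 2], [2, 5], mode="truncate_sorted")
        assert a.tolist() == [3, 2] and c.tolist() == [5, 2]


class TestBdScore:
    def test_identical_rows_give_zero(self):
        r = np.array([0.4, 0.1, 0.5])
        assert bd_score(r, r) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_distribution_pair(self):
        # BC = sqrt(0.125) + sqrt(0.375) = 0.96593, BD = -ln BC = 0.03466
        bd = bd_score(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        assert bd == pytest.approx(0.03466, abs=1e-4)

    def test_disjoint_support_hits_cap(self):
        assert bd_score(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 745.0

    def test_literal_mode_reproduces_raw_formula(self):
        ra, rc = np.array([2.0, 1.0]), np.array([3.0, 0.5])
        assert bd_score(ra, rc, mode="literal") == pytest.approx(-np.log(6.5))

    def test_all_zero_row_is_an_error(self):
        with pytest.raises(ValueError):
            bd_score(np.zeros(3), np.ones(3))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(positive_rows, positive_rows, st.floats(min_value=0.1, max_value=10))
    def test_nonnegative_scale_invariant_symmetric(self, ra, rc, scale):
        a, c = comparable_rows(ra, rc)
        bd = bd_score(a, c)
        assert bd >= 0.0
        assert bd_score(c, a) == pytest.approx(bd)
        assert bd_score(scale * a, c) == pytest.approx(bd, abs=1e-9)


class TestMacScore:
    def test_identical_rows_give_one(self):
        r = np.array([1.0, 3.0, 2.0])
        assert mac_score(r, r) == pytest.approx(1.0)

    def test_orthogonal_rows_give_zero(self):
        assert mac_score(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_hand_computed_half(self):
        assert mac_score(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_zero_norm_row_is_an_error(self):
        with pytest.raises(ValueError):
            mac_score(np.zeros(2), np.ones(2))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(positive_rows, positive_rows, st.floats(min_value=0.1, max_value=10))
    def test_bounded_scale_invariant_symmetric(self, ra, rc, scale):
        a, c = comparable_rows(ra, rc)
        mac = mac_score(a, c)
        assert 0.0 <= mac <= 1.0
        assert mac_score(c, a) == pytest.approx(mac)
        assert mac_score(scale * a, c) == pytest.approx(mac, abs=1e-9)

    def test_one_iff_proportional(self):
        a = np.array([1.0, 2.0, 3.0])
        assert mac_score(a, 4.2 * a) == pytest.approx(1.0)
        assert mac_score(a, np.array([1.0, 2.0, 3.5])) < 1.0


class TestBuildSimilarityMatrix:
    def _peer_graphs(self, m, n, seed):
        ga = build_feature_graph(random_vector_set(m, seed=seed), "ed")
        gc = build_feature_graph(random_vector_set(n, seed=seed + 1, side="C"), "ed")
        return ga, gc

    @pytest.mark.parametrize("scorer", ["BD", "MAC"])
    def test_matches_elementwise_oracle(self, scorer):
        ga, gc = self._peer_graphs(3, 2, seed=21)
        sm = build_similarity_matrix(ga, gc, scorer=scorer)
        assert sm.shape == (3, 2)
        for i in range(3):
            for j in range(2):
                a, c = comparable_rows(ga.row_profile(i + 1), gc.row_profile(j + 1))
                expected = bd_score(a, c) if scorer == "BD" else mac_score(a, c)
                assert sm.scores[i, j] == pytest.approx(expected)

    def test_permuted_copy_scores_perfectly_on_diagonal(self):
        """A shuffled copy of a graph scores MAC=1 / BD=0 at its partner."""
        vs = random_vector_set(5, seed=33)
        perm = [3, 0, 4, 1, 2]
        from ssematch import SSEVector, VectorSet

        shuffled = VectorSet("C", [
            SSEVector(index=k + 1, side="C", start=vs[p].start, end=vs[p].end)
            for k, p in enumerate(perm)
        ])
        ga = build_feature_graph(vs, "ed")
        gc = build_feature_graph(shuffled, "ed")
        mac = build_similarity_matrix(ga, gc, scorer="MAC")
        bd = build_similarity_matrix(ga, gc, scorer="BD")
        for c_idx, a_idx in enumerate(perm):
            assert mac.scores[a_idx, c_idx] == pytest.approx(1.0)
            assert bd.scores[a_idx, c_idx] == pytest.approx(0.0, abs=1e-9)

    def test_polarity_labels(self):
        ga, gc = self._peer_graphs(3, 3, seed=5)
        assert build_similarity_matrix(ga, gc, scorer="BD").polarity == "distance"
        assert build_similarity_matrix(ga, gc, scorer="MAC").polarity == "similarity"

    def test_mismatched_features_rejected(self):
        ga = build_feature_graph(random_vector_set(3, seed=1), "ed")
        gc = build_feature_graph(random_vector_set(3, seed=2, side="C"), "rl")
        with pytest.raises(ValueError):
            build_similarity_matrix(ga, gc)
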