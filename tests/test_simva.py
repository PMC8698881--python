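import pytest

from ssematch import CorrespondenceSet, run_simva
from ssematch.simva import VotingState, majority_vote, plc_step, unanimous_vote


def cs(pairs, feature="angle", scorer="MAC"):
    return CorrespondenceSet(
        pairs=tuple((a, c, s) for a, c, s in pairs), feature=feature, scorer=scorer
    )


def make_state(s1, s2, s3, scorer="MAC"):
    return VotingState(
        candidates=(cs(s1, "angle", scorer), cs(s2, "ed", scorer), cs(s3, "rl", scorer)),
        scorer=scorer,
    )


class TestUnanimousVote:
    def test_identical_sets_fully_accepted(self):
        pairs = [(1, 1, 0.9), (2, 2, 0.8)]
        state = unanimous_vote(make_state(pairs, pairs, pairs))
        assert {(a, c) for a, c, _, _ in state.accepted} == {(1, 1), (2, 2)}

    def test_partial_agreement(self):
        s1 = [(1, 1, 0.9), (2, 2, 0.8)]
        s2 = [(1, 1, 0.7), (2, 3, 0.6)]
        s3 = [(1, 1, 0.8), (2, 2, 0.5)]
        state = unanimous_vote(make_state(s1, s2, s3))
        assert {(a, c) for a, c, _, _ in state.accepted} == {(1, 1)}
        assert 1 not in state.remaining_a and 1 not in state.remaining_c

    def test_disjoint_sets_accept_nothing(self):
        state = unanimous_vote(
            make_state([(1, 1, 0.9)], [(1, 2, 0.9)], [(1, 3, 0.9)])
        )
        assert state.accepted == []


class TestMajorityVote:
    def test_two_of_three_accepted(self):
        s1 = [(1, 1, 0.9), (2, 2, 0.8)]
        s2 = [(1, 1, 0.7), (2, 3, 0.6)]
        s3 = [(1, 1, 0.8), (2, 2, 0.5)]
        state = make_state(s1, s2, s3)
        unanimous_vote(state)
        majority_vote(state)
        assert {(a, c) for a, c, _, _ in state.accepted} == {(1, 1), (2, 2)}

    def test_single_vote_not_accepted(self):
        state = make_state([(1, 1, 0.9)], [(1, 2, 0.8)], [(1, 3, 0.7)])
        unanimous_vote(state)
        majority_vote(state)
        assert state.accepted == []

    def test_unanimous_then_majority_layering(self):
        s1 = [(1, 2, 0.9), (2, 3, 0.2)]
        s2 = [(1, 2, 0.8), (2, 3, 0.3)]
        s3 = [(1, 4, 0.95), (2, 3, 0.4)]
        # (2,3): 3 votes -> unanimous; (1,2): 2 votes -> majority
        state = make_state(s1, s2, s3)
        unanimous_vote(state)
        majority_vote(state)
        assert {(a, c) for a, c, _, _ in state.accepted} == {(2, 3), (1, 2)}

    def test_vote_counting_with_mixed_sets(self):
        # (1,2) has two votes; (2,2) and (2,3) have one each -> only (1,2) passes.
        # (With three injective candidate sets, two distinct >=2-vote pairs can
        # never share an index, so majority conflicts cannot arise here.)
        s1 = [(1, 2, 0.6)]
        s2 = [(1, 2, 0.6), (2, 3, 0.1)]
        s3 = [(2, 2, 0.9)]
        state = make_state(s1, s2, s3)
        unanimous_vote(state)
        majority_vote(state)
        assert {(a, c) for a, c, _, _ in state.accepted} == {(1, 2)}


class TestPlcStep:
    def test_conflict_counting_and_score_tiebreak(self):
        # pool {(1,2),(1,3),(2,2)}: conflicts 2,1,1; tie (1,3) vs (2,2) by score
        s1 = [(1, 2, 0.5)]
        s2 = [(1, 3, 0.9)]
        s3 = [(2, 2, 0.7)]
        state = make_state(s1, s2, s3)
        assert plc_step(state)
        assert {(a, c) for a, c, _, _ in state.accepted} == {(1, 3)}

    def test_single_candidate_accepted_with_zero_conflict(self):
        state = make_state([(1, 1, 0.4)], [(1, 1, 0.4)], [])
        assert plc_step(state)
        assert {(a, c) for a, c, _, _ in state.accepted} == {(1, 1)}

    def test_disjoint_candidates_accepted_over_two_steps(self):
        state = make_state([(1, 1, 0.9)], [(2, 2, 0.8)], [])
        assert plc_step(state)
        assert plc_step(state)
        assert not plc_step(state)
        assert {(a, c) for a, c, _, _ in state.accepted} == {(1, 1), (2, 2)}

    def test_no_live_pairs_is_noop(self):
        state = make_state([(1, 1, 0.9)], [(1, 1, 0.9)], [(1, 1, 0.9)])
        unanimous_vote(state)
        assert not plc_step(state)


class TestRunSimva:
    def test_three_identical_sets_pass_through(self):
        pairs = [(1, 4, 0.9), (2, 1, 0.8), (3, 2, 0.7)]
        final = run_simva(cs(pairs, "angle"), cs(pairs, "ed"), cs(pairs, "rl"))
        assert final.pair_set == {(1, 4), (2, 1), (3, 2)}
        assert final.stages == ("unanimous",) * 3

    def test_hand_traced_fusion(self):
        """Unanimous takes (1,1); majority takes (2,2); PLC mops up (3,·)."""
        s1 = [(1, 1, 0.9), (2, 2, 0.8), (3, 3, 0.3)]
        s2 = [(1, 1, 0.9), (2, 3, 0.7), (3, 4, 0.4)]
        s3 = [(1, 1, 0.9), (2, 2, 0.6), (3, 5, 0.5)]
        final = run_simva(cs(s1, "angle"), cs(s2, "ed"), cs(s3, "rl"))
        assert (1, 1) in final.pair_set
        assert (2, 2) in final.pair_set
        # PLC: remaining a=3 candidates (3,3),(3,4),(3,5) all conflict count 2,
        # scores 0.3, 0.4, 0.5 -> best score wins
        assert (3, 5) in final.pair_set
        assert final.stages == ("unanimous", "majority", "plc")

    def test_bd_polarity_flips_tiebreaks(self):
        s1 = [(1, 2, 0.5)]
        s2 = [(1, 3, 0.9)]
        s3 = [(2, 2, 0.1)]
        final = run_simva(
            cs(s1, "angle", "BD"), cs(s2, "ed", "BD"), cs(s3, "rl", "BD"), scorer="BD"
        )
        # conflicts: (1,2)=2, (1,3)=1, (2,2)=1; BD lower is better -> (2,2) first
        assert (2, 2) in final.pair_set
        assert (1, 3) in final.pair_set

    def test_empty_candidates_give_empty_output(self):
        final = run_simva(cs([], "angle"), cs([], "ed"), cs([], "rl"))
        assert len(final) == 0

    def test_final_set_injective_and_subset_of_union(self):
        import numpy as np

        rng = np.random.default_rng(7)
        # three random injections over 6x6
        sets = []
        for feature in ("angle", "ed", "rl"):
            perm = rng.permutation(6)
            sets.append(cs([(i + 1, int(perm[i]) + 1, rng.random()) for i in range(6)], feature))
        final = run_simva(*sets)
        a_idx = [a for a, _, _ in final.pairs]
        c_idx = [c for _, c, _ in final.pairs]
        assert len(set(a_idx)) == len(a_idx) and len(set(c_idx)) == len(c_idx)
        union = set().union(*(s.pair_set for s in sets))
        assert final.pair_set <= union

    def test_scorer_mismatch_rejected(self):
        with pytest.raises(ValueError):
            run_simva(cs([], "angle", "BD"), cs([], "ed"), cs([], "rl"))
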