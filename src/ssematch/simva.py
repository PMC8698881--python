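"""Similarity-based voting fusion of the three per-feature correspondences.

The angle, midpoint-distance and relative-length features each yield an
independent one-to-one candidate correspondence. The fusion proceeds in
three stages, each consuming indices so the accepted set stays injective:

1. **Unanimous voting** — pairs present in all three candidate sets are
   accepted outright.
2. **Majority voting** — pairs over still-free indices present in at least
   two candidate sets are accepted; conflicting majority pairs are resolved
   by vote count, then mean score, then lowest indices.
3. **Principle of least conflict (PLC)** — while any candidate pair over
   free indices remains, count for each such pair how many other remaining
   candidate pairs share its model or map index, and accept the pair with
   the fewest conflicts (ties: better score, then lowest indices).

Every tie-break is a total order, so the fusion is deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assignment import CorrespondenceSet

STAGES = ("unanimous", "majority", "plc")


@dataclass
class VotingState:
    """Mutable state threaded through the three voting stages."""

    candidates: tuple[CorrespondenceSet, CorrespondenceSet, CorrespondenceSet]
    scorer: str
    accepted: list[tuple[int, int, float, str]] = field(default_factory=list)
    remaining_a: set[int] = field(default_factory=set)
    remaining_c: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.remaining_a:
            self.remaining_a = {a for cs in self.candidates for a, _, _ in cs.pairs}
        if not self.remaining_c:
            self.remaining_c = {c for cs in self.candidates for _, c, _ in cs.pairs}

    # -- helpers -----------------------------------------------------------

    def votes_and_score(self, a: int, c: int) -> tuple[int, float]:
        """Vote count and mean score of pair (a, c) across candidate sets."""
        scores = [
            cs.score_of(a, c) for cs in self.candidates if (a, c) in cs.pair_set
        ]
        return len(scores), float(np.mean(scores)) if scores else 0.0

    def score_key(self, score: float) -> float:
        """Sort key making 'better' smaller: MAC maximized, BD minimized."""
        return score if self.scorer == "BD" else -score

    def live_pairs(self) -> set[tuple[int, int]]:
        """Union of candidate pairs restricted to still-unassigned indices."""
        return {
            (a, c)
            for cs in self.candidates
            for a, c, _ in cs.pairs
            if a in self.remaining_a and c in self.remaining_c
        }

    def accept(self, a: int, c: int, score: float, stage: str) -> None:
        assert a in self.remaining_a and c in self.remaining_c, "index already consumed"
        self.accepted.append((a, c, score, stage))
        self.remaining_a.discard(a)
        self.remaining_c.discard(c)

    def result(self) -> CorrespondenceSet:
        ordered = sorted(self.accepted)
        return CorrespondenceSet(
            pairs=tuple((a, c, s) for a, c, s, _ in ordered),
            feature="fused",
            scorer=self.scorer,
            stages=tuple(stage for _, _, _, stage in ordered),
        )


def unanimous_vote(state: VotingState) -> VotingState:
    """Accept every pair present in all three candidate sets."""
    s1, s2, s3 = (cs.pair_set for cs in state.candidates)
    for a, c in sorted(s1 & s2 & s3):
        _, score = state.votes_and_score(a, c)
        state.accept(a, c, score, "unanimous")
    return state


def majority_vote(state: VotingState) -> VotingState:
    """Accept pairs over free indices appearing in at least two sets.

    Because the candidate sets are three independent injections, two
    majority pairs can share an index; the contested index goes to the pair
    with more votes, then the better mean score, then the lowest indices.
    """
    tally: dict[tuple[int, int], tuple[int, float]] = {}
    for a, c in state.live_pairs():
        votes, score = state.votes_and_score(a, c)
        if votes >= 2:
            tally[(a, c)] = (votes, score)
    ranked = sorted(
        tally.items(),
        key=lambda kv: (-kv[1][0], state.score_key(kv[1][1]), kv[0][0], kv[0][1]),
    )
    for (a, c), (_, score) in ranked:
        if a in state.remaining_a and c in state.remaining_c:
            state.accept(a, c, score, "majority")
    return state


def plc_step(state: VotingState) -> bool:
    """Accept the least-conflicted remaining candidate pair.

    The conflict count of pair <a, c> is the number of other remaining
    candidate pairs that share a or c. Returns False (no-op) when no
    candidate pair over free indices remains, which terminates the loop.
    """
    pool = sorted(state.live_pairs())
    if not pool:
        return False
    best = None
    for a, c in pool:
        conflicts = sum(
            1 for oa, oc in pool if (oa, oc) != (a, c) and (oa == a or oc == c)
        )
        _, score = state.votes_and_score(a, c)
        key = (conflicts, state.score_key(score), a, c)
        if best is None or key < best[0]:
            best = (key, a, c, score)
    _, a, c, score = best
    state.accept(a, c, score, "plc")
    return True


def run_simva(
    c_angle: CorrespondenceSet,
    c_ed: CorrespondenceSet,
    c_rl: CorrespondenceSet,
    scorer: str = "MAC",
) -> CorrespondenceSet:
    """Fuse the three per-feature candidate sets into the final one.

    Runs unanimous voting, majority voting, then PLC iterated to
    exhaustion. The result is injective and a subset of the union of the
    candidate sets.
    """
    for cs in (c_angle, c_ed, c_rl):
        if cs.scorer != scorer:
            raise ValueError(
                f"candidate set for {cs.feature} was scored with {cs.scorer}, "
                f"expected {scorer}"
            )
    state = VotingState(candidates=(c_angle, c_ed, c_rl), scorer=scorer)
    unanimous_vote(state)
    _check_invariants(state)
    majority_vote(state)
    _check_invariants(state)
    while plc_step(state):
        _check_invariants(state)
    return state.result()


def _check_invariants(state: VotingState) -> None:
    a_indices = [a for a, _, _, _ in state.accepted]
    c_indices = [c for _, c, _, _ in state.accepted]
    assert len(set(a_indices)) == len(a_indices), "accepted set not injective in A"
    assert len(set(c_indices)) == len(c_indices), "accepted set not injective in C"
    union = {(a, c) for cs in state.candidates for a, c, _ in cs.pairs}
    assert all((a, c) in union for a, c, _, _ in state.accepted), (
        "accepted pair outside candidate union"
    )
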