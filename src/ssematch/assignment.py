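"""Turning a node-score matrix into a one-to-one candidate correspondence.

Each feature's m×n score matrix is resolved into an injective assignment of
size min(m, n) by exact linear assignment (Hungarian method via
``scipy.optimize.linear_sum_assignment``): total MAC maximized or total BD
minimized. Ties between equally good assignments are broken by preferring
the lexicographically smallest pair list (lower a_index, then lower
c_index); the exact tie-break refinement is applied on small problems where
exact score ties can plausibly occur (see ``LEX_REFINE_MAX``), while larger
continuous-score instances rely on the solver's deterministic output.

A brute-force enumerator over all injections serves as an independent
oracle for validation on small instances.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

#: Largest min(m, n) for which the exact lexicographic tie-break refinement
#: runs; above this the Hungarian solution is used directly.
LEX_REFINE_MAX = 12

_BRUTE_FORCE_MAX = 8


@dataclass
class CorrespondenceSet:
    """Injective set of (a_index, c_index, score) pairs, 1-based indices."""

    pairs: tuple[tuple[int, int, float], ...]
    feature: str = "fused"
    scorer: str = "MAC"
    stages: tuple[str, ...] | None = None  # provenance per pair (fused sets)

    def __post_init__(self) -> None:
        self.pairs = tuple((int(a), int(c), float(s)) for a, c, s in self.pairs)
        a_indices = [a for a, _, _ in self.pairs]
        c_indices = [c for _, c, _ in self.pairs]
        if len(set(a_indices)) != len(a_indices) or len(set(c_indices)) != len(c_indices):
            raise ValueError("correspondence must be injective in both coordinates")
        if any(a < 1 or c < 1 for a, c, _ in self.pairs):
            raise ValueError("indices are 1-based")
        if self.stages is not None and len(self.stages) != len(self.pairs):
            raise ValueError("stages must align with pairs")

    @property
    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((a, c) for a, c, _ in self.pairs)

    def as_dict(self) -> dict[int, int]:
        return {a: c for a, c, _ in self.pairs}

    def score_of(self, a: int, c: int) -> float:
        for pa, pc, s in self.pairs:
            if (pa, pc) == (a, c):
                return s
        raise KeyError((a, c))

    def __len__(self) -> int:
        return len(self.pairs)

    def total_score(self) -> float:
        return float(sum(s for _, _, s in self.pairs))


def _as_cost(sm) -> np.ndarray:
    scores = np.asarray(sm.scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("score matrix contains non-finite entries")
    return scores if sm.polarity == "distance" else -scores


def _lap_value(cost: np.ndarray) -> float:
    if min(cost.shape) == 0:
        return 0.0
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def _lex_refine(cost: np.ndarray) -> list[tuple[int, int]]:
    """Lexicographically smallest optimal assignment (0-based pairs).

    Fixes rows in ascending order to the smallest column that preserves the
    optimal total; rows that no optimal solution matches (possible when
    m > n) are skipped.
    """
    m, n = cost.shape
    tol = 1e-9 * max(1.0, float(np.abs(cost).max()))
    rows = list(range(m))
    cols = list(range(n))
    opt = _lap_value(cost[np.ix_(rows, cols)])
    pairs: list[tuple[int, int]] = []
    while rows and cols:
        a, rest = rows[0], rows[1:]
        chosen = None
        for c in cols:
            other_cols = [x for x in cols if x != c]
            sub_val = _lap_value(cost[np.ix_(rest, other_cols)]) if rest else 0.0
            if cost[a, c] + sub_val <= opt + tol:
                chosen = c
                opt = sub_val
                break
        if chosen is None:
            # row a is unmatched in every optimal solution (m > n case)
            rows = rest
            continue
        pairs.append((a, chosen))
        rows = rest
        cols.remove(chosen)
    return pairs


def optimal_assignment(sm, mode: str = "optimal") -> CorrespondenceSet:
    """Best one-to-one assignment of size min(m, n) from a score matrix.

    ``mode="greedy"`` repeatedly takes the best remaining single entry
    instead (an intentionally suboptimal ablation baseline).
    """
    cost = _as_cost(sm)
    m, n = cost.shape
    if mode == "greedy":
        pairs0 = _greedy_pairs(cost)
    elif mode == "optimal":
        if min(m, n) <= LEX_REFINE_MAX:
            pairs0 = _lex_refine(cost)
        else:
            rows, cols = linear_sum_assignment(cost)
            pairs0 = sorted(zip(rows.tolist(), cols.tolist()))
    else:
        raise ValueError("mode must be 'optimal' or 'greedy'")
    pairs = tuple(
        (i + 1, j + 1, float(sm.scores[i, j])) for i, j in sorted(pairs0)
    )
    return CorrespondenceSet(pairs=pairs, feature=sm.feature, scorer=sm.scorer)


def _greedy_pairs(cost: np.ndarray) -> list[tuple[int, int]]:
    m, n = cost.shape
    free_rows = set(range(m))
    free_cols = set(range(n))
    pairs: list[tuple[int, int]] = []
    while free_rows and free_cols:
        best = min(
            ((cost[i, j], i, j) for i in sorted(free_rows) for j in sorted(free_cols)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        _, i, j = best
        pairs.append((i, j))
        free_rows.discard(i)
        free_cols.discard(j)
    return pairs


def brute_force_assignment(sm) -> CorrespondenceSet:
    """Exhaustive-enumeration oracle; same objective and tie-break rule.

    Guarded to min(m, n) ≤ 8 — factorial enumeration only.
    """
    cost = _as_cost(sm)
    m, n = cost.shape
    if min(m, n) > _BRUTE_FORCE_MAX:
        raise ValueError(f"brute force limited to min(m, n) <= {_BRUTE_FORCE_MAX}")
    if max(m, n) > 10:
        raise ValueError("brute force limited to max(m, n) <= 10")

    transposed = m > n
    work = cost.T if transposed else cost  # rows are now the smaller side
    k, big = work.shape
    best_pairs: list[tuple[int, int]] | None = None
    best_val = np.inf
    for cols in itertools.permutations(range(big), k):
        raw = list(zip(range(k), cols))
        pairs = sorted((c, r) for r, c in raw) if transposed else raw
        val = float(sum(work[r, c] for r, c in raw))
        if val < best_val - 1e-12 or (
            abs(val - best_val) <= 1e-12
            and best_pairs is not None
            and pairs < best_pairs
        ):
            best_val = val
            best_pairs = pairs
    assert best_pairs is not None
    return CorrespondenceSet(
        pairs=tuple((i + 1, j + 1, float(sm.scores[i, j])) for i, j in best_pairs),
        feature=sm.feature,
        scorer=sm.scorer,
    )
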