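"""Node-similarity scoring between peer feature graphs.

Row *i* of the A-side adjacency matrix is a geometric signature of model
SSE *i*: its feature values against every other model SSE. Likewise row *j*
on the map side. Two scoring functions compare such rows:

* **BD** — Bhattacharyya distance. In the default ``normalized`` mode each
  row is rescaled to a discrete distribution and BD = −ln Σ√(p·q) ≥ 0, with
  0 meaning identical profiles. A ``literal`` mode computes −ln Σ(ra·rc) on
  the raw rows (no normalization; can be negative) for users who want the
  unnormalized inner-product variant.
* **MAC** — modal assurance criterion, (ra·rc)² / ((ra·ra)(rc·rc)) ∈ [0, 1],
  1 iff the rows are proportional.

The two rows generally have different lengths (m−1 vs n−1) and their columns
refer to different, as-yet-unmatched nodes, so positional comparison is
meaningless. Rows are therefore aligned by sorting each in descending order
and zero-padding the shorter (``sort_pad``), turning each row into a
permutation-invariant profile; ``truncate_sorted`` instead truncates the
longer sorted row.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_graphs import FeatureGraph

SCORERS = ("BD", "MAC")
BD_MODES = ("normalized", "literal")
ROW_ALIGNMENTS = ("sort_pad", "truncate_sorted")

#: BD value substituted when the Bhattacharyya coefficient underflows to 0
#: (disjoint supports); just below −ln of the smallest positive double.
BD_MAX = 745.0


@dataclass
class SimilarityMatrix:
    """m×n node-score matrix for one feature under one scorer."""

    feature: str
    scorer: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scorer not in SCORERS:
            raise ValueError(f"scorer must be one of {SCORERS}")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")

    @property
    def polarity(self) -> str:
        """"distance" (lower is better, BD) or "similarity" (higher, MAC)."""
        return "distance" if self.scorer == "BD" else "similarity"

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


def comparable_rows(
    ra: np.ndarray, rc: np.ndarray, mode: str = "sort_pad"
) -> tuple[np.ndarray, np.ndarray]:
    """Align two row profiles of possibly different lengths for scoring."""
    if mode not in ROW_ALIGNMENTS:
        raise ValueError(f"row alignment must be one of {ROW_ALIGNMENTS}")
    ra = np.sort(np.asarray(ra, dtype=float))[::-1]
    rc = np.sort(np.asarray(rc, dtype=float))[::-1]
    if ra.size == 0 or rc.size == 0:
        raise ValueError("row profiles must be non-empty")
    if mode == "truncate_sorted":
        k = min(ra.size, rc.size)
        return ra[:k].copy(), rc[:k].copy()
    k = max(ra.size, rc.size)
    out_a = np.zeros(k)
    out_c = np.zeros(k)
    out_a[: ra.size] = ra
    out_c[: rc.size] = rc
    return out_a, out_c


def bd_score(
    ra: np.ndarray,
    rc: np.ndarray,
    mode: str = "normalized",
    bd_max: float = BD_MAX,
) -> float:
    """Bhattacharyya distance between two aligned row profiles.

    Inputs must already be aligned (same length); use
    :func:`comparable_rows` first.
    """
    if mode not in BD_MODES:
        raise ValueError(f"bd mode must be one of {BD_MODES}")
    ra = np.asarray(ra, dtype=float)
    rc = np.asarray(rc, dtype=float)
    if ra.shape != rc.shape:
        raise ValueError("rows must be aligned to a common length")
    if mode == "literal":
        inner = float(np.dot(ra, rc))
        if inner <= 0.0:
            return bd_max
        return -float(np.log(inner))
    sa, sc = ra.sum(), rc.sum()
    if sa <= 0.0 or sc <= 0.0:
        raise ValueError("all-zero row profile: node has no geometric context")
    bc = float(np.sum(np.sqrt((ra / sa) * (rc / sc))))
    if bc <= 0.0:
        return bd_max
    return max(0.0, -float(np.log(min(bc, 1.0))))


def mac_score(ra: np.ndarray, rc: np.ndarray) -> float:
    """Modal assurance criterion of two aligned row profiles, in [0, 1]."""
    ra = np.asarray(ra, dtype=float)
    rc = np.asarray(rc, dtype=float)
    if ra.shape != rc.shape:
        raise ValueError("rows must be aligned to a common length")
    na = float(np.dot(ra, ra))
    nc = float(np.dot(rc, rc))
    if na <= 0.0 or nc <= 0.0:
        raise ValueError("zero-norm row profile")
    val = float(np.dot(ra, rc)) ** 2 / (na * nc)
    return max(0.0, min(1.0, val))


def build_similarity_matrix(
    ga: FeatureGraph,
    gc: FeatureGraph,
    scorer: str = "MAC",
    bd_mode: str = "normalized",
    row_alignment: str = "sort_pad",
    bd_max: float = BD_MAX,
) -> SimilarityMatrix:
    """Score every (model node i, map node j) pair of two peer graphs."""
    if scorer not in SCORERS:
        raise ValueError(f"scorer must be one of {SCORERS}")
    if ga.feature != gc.feature:
        raise ValueError("peer graphs must share a feature")
    if ga.side != "A" or gc.side != "C":
        raise ValueError("expected an A-side and a C-side graph, in that order")
    m, n = ga.size, gc.size
    scores = np.empty((m, n))
    rows_a = [ga.row_profile(i + 1) for i in range(m)]
    rows_c = [gc.row_profile(j + 1) for j in range(n)]
    for i in range(m):
        for j in range(n):
            aligned_a, aligned_c = comparable_rows(rows_a[i], rows_c[j], row_alignment)
            if scorer == "BD":
                scores[i, j] = bd_score(aligned_a, aligned_c, mode=bd_mode, bd_max=bd_max)
            else:
                scores[i, j] = mac_score(aligned_a, aligned_c)
    return SimilarityMatrix(feature=ga.feature, scorer=scorer, scores=scores)
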