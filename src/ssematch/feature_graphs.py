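"""Feature-weighted fully connected graphs over one SSE vector set.

Each vector set (model side A, map side C) becomes three complete graphs
whose nodes are the SSE vectors and whose edge weights are pairwise
geometric features:

* **angle** — |cos θ| of the two segment directions (dimensionless, [0, 1]);
* **ed** — Euclidean distance between segment midpoints (Å);
* **rl** — relative length |L_i − L_j| / (L_i + L_j) (dimensionless, [0, 1)).

All three are invariant under rigid motion of the whole set; angle and rl
are also scale-invariant. Each graph is stored as a symmetric adjacency
matrix with an exactly zero diagonal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vector_model import SSEVector, VectorSet, DegenerateVectorError

FEATURES = ("angle", "ed", "rl")


@dataclass
class FeatureGraph:
    """Symmetric weighted adjacency matrix for one feature over one set."""

    side: str
    feature: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"feature must be one of {FEATURES}")
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite edge weight")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("diagonal entries must be exactly zero")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be symmetric")

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    def row_profile(self, i: int) -> np.ndarray:
        """Off-diagonal weights of node ``i`` (1-based), length size − 1."""
        idx = i - 1
        return np.delete(self.weights[idx], idx)


def angle_weight(u: SSEVector, v: SSEVector, signed: bool = False) -> float:
    """Cosine of the angle between two segment directions.

    By default the absolute value is returned: a stick traced from a density
    map has no meaningful head/tail, so antiparallel directions describe the
    same physical geometry. ``signed=True`` keeps the raw cosine.
    """
    cos = float(np.dot(u.direction, v.direction))
    cos = max(-1.0, min(1.0, cos))
    return cos if signed else abs(cos)


def ed_weight(u: SSEVector, v: SSEVector) -> float:
    """Euclidean distance between the two segment midpoints (Å)."""
    return float(np.linalg.norm(u.midpoint - v.midpoint))


def rl_weight(u: SSEVector, v: SSEVector) -> float:
    """Relative length difference |L_u − L_v| / (L_u + L_v), in [0, 1)."""
    lu, lv = u.length, v.length
    return abs(lu - lv) / (lu + lv)


def build_feature_graph(
    vs: VectorSet, feature: str, signed_angle: bool = False
) -> FeatureGraph:
    """Build the complete weighted graph of ``feature`` over a vector set."""
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}")
    n = len(vs)
    for vec in vs:
        if vec.length <= 1e-6:  # unreachable through SSEVector, but guard raw use
            raise DegenerateVectorError(f"degenerate vector at index {vec.index}")

    weights = np.zeros((n, n))
    if feature == "angle":
        func = lambda u, v: angle_weight(u, v, signed=signed_angle)
    elif feature == "ed":
        func = ed_weight
    else:
        func = rl_weight
    for i in range(n):
        for j in range(i + 1, n):
            w = func(vs[i], vs[j])
            weights[i, j] = weights[j, i] = w
    return FeatureGraph(side=vs.side, feature=feature, weights=weights)


def build_all_graphs(vs: VectorSet, signed_angle: bool = False) -> dict[str, FeatureGraph]:
    """All three feature graphs of one set, keyed by feature name."""
    return {f: build_feature_graph(vs, f, signed_angle=signed_angle) for f in FEATURES}
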