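"""3D vector representation of secondary structure elements.

A helix or strand — whether traced from an atomic model's Cα backbone or
detected as a density rod in a medium-resolution cryo-EM map — is reduced
to a directed line segment in Cartesian space: its first and last trace
point. All downstream matching operates on these segments only.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

#: Minimum segment length (Å) below which a vector is considered degenerate.
DEGENERATE_TOL = 1e-6

SIDES = ("A", "C")
KINDS = ("helix", "strand", "unknown")


class DegenerateVectorError(ValueError):
    """Raised when an SSE trace collapses to (numerically) a single point."""


@dataclass(frozen=True, eq=False)
class SSEVector:
    """One SSE as a directed segment from ``start`` to ``end`` (Å).

    ``side`` is "A" for model-derived elements and "C" for map-derived
    sticks; ``index`` is the 1-based position within its set.
    """

    index: int
    side: str
    start: np.ndarray
    end: np.ndarray
    kind: str = "unknown"
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.index < 1:
            raise ValueError("index is 1-based and must be >= 1")
        start = np.asarray(self.start, dtype=float).reshape(3)
        end = np.asarray(self.end, dtype=float).reshape(3)
        if not (np.all(np.isfinite(start)) and np.all(np.isfinite(end))):
            raise ValueError("vector endpoints must be finite")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if float(np.linalg.norm(end - start)) <= DEGENERATE_TOL:
            raise DegenerateVectorError(
                f"degenerate SSE vector (side {self.side}, index {self.index}): "
                f"start and end coincide within {DEGENERATE_TOL} Å"
            )

    @property
    def length(self) -> float:
        """Segment length in Å."""
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        """Unit direction vector e − s (orientation is trace order, not physical)."""
        d = self.end - self.start
        return d / np.linalg.norm(d)

    @property
    def midpoint(self) -> np.ndarray:
        return (self.start + self.end) / 2.0

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SSEVector":
        """Return a copy with both endpoints mapped through x ↦ Rx + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float).reshape(3)
        return replace(
            self,
            start=rotation @ self.start + translation,
            end=rotation @ self.end + translation,
        )


@dataclass
class VectorSet:
    """Ordered collection of SSE vectors for one side (model A or map C)."""

    side: str
    vectors: list[SSEVector]

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if len(self.vectors) < 2:
            raise ValueError("a vector set needs at least 2 elements (graphs need an edge)")
        for pos, vec in enumerate(self.vectors, start=1):
            if vec.side != self.side:
                raise ValueError(f"vector {pos} has side {vec.side!r}, set is {self.side!r}")
            if vec.index != pos:
                raise ValueError(
                    f"vector indices must be contiguous 1..n; position {pos} has index {vec.index}"
                )

    def __len__(self) -> int:
        return len(self.vectors)

    def __iter__(self) -> Iterator[SSEVector]:
        return iter(self.vectors)

    def __getitem__(self, i: int) -> SSEVector:
        return self.vectors[i]

    def endpoints(self) -> np.ndarray:
        """(n, 2, 3) array of start/end points."""
        return np.array([[v.start, v.end] for v in self.vectors])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "VectorSet":
        return VectorSet(
            self.side, [v.transformed(rotation, translation) for v in self.vectors]
        )


def vector_from_record_a(record, index: int = 1) -> SSEVector:
    """Build a model-side vector from an annotated SSE record.

    The segment runs from the first to the last Cα of the residue-ordered
    trace. For helices the first Cα sits off the helical axis; the trace
    endpoints are used as-is, without axis re-estimation.
    """
    coords = np.asarray(record.ca_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2 or coords.shape[1] != 3:
        raise ValueError("record needs at least 2 Cα points")
    return SSEVector(
        index=index,
        side="A",
        start=coords[0],
        end=coords[-1],
        kind=record.kind,
        source_label=getattr(record, "label", "") or f"{record.kind}:{index}",
    )


def vector_from_record_c(record, index: int = 1) -> SSEVector:
    """Build a map-side vector from a detected stick's axis trace.

    The segment runs from the first to the last axis point. Trace direction
    is arbitrary (a detector may emit either orientation), so every feature
    computed downstream must be insensitive to start/end swaps.
    """
    pts = np.asarray(record.axis_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("stick needs at least 2 axis points")
    return SSEVector(
        index=index,
        side="C",
        start=pts[0],
        end=pts[-1],
        kind="unknown",
        source_label=f"stick:{record.stick_id}",
    )


def vector_set_from_records(records: Iterable, side: str) -> VectorSet:
    """Convert a list of SSE records to a VectorSet with contiguous indices."""
    records = list(records)
    make = vector_from_record_a if side == "A" else vector_from_record_c
    return VectorSet(side, [make(rec, index=i) for i, rec in enumerate(records, start=1)])
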