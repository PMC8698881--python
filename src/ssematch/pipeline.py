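"""End-to-end wiring: vector sets in, fused correspondence out."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .assignment import CorrespondenceSet, optimal_assignment
from .feature_graphs import FEATURES, build_all_graphs
from .similarity import (
    BD_MAX,
    BD_MODES,
    ROW_ALIGNMENTS,
    SCORERS,
    build_similarity_matrix,
)
from .simva import run_simva
from .vector_model import VectorSet


@dataclass(frozen=True)
class RunConfig:
    """All tunable knobs of a matching run.

    Defaults follow the recommended setup: MAC scoring (the more reliable
    of the two row scorers), normalized Bhattacharyya distance, sort-and-pad
    row alignment, orientation-insensitive angles and exact assignment.
    """

    scorer: str = "MAC"
    bd_mode: str = "normalized"
    row_alignment: str = "sort_pad"
    angle_mode: str = "abs"
    assignment_mode: str = "optimal"
    bd_max: float = BD_MAX
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.scorer not in SCORERS:
            raise ValueError(f"scorer must be one of {SCORERS}")
        if self.bd_mode not in BD_MODES:
            raise ValueError(f"bd_mode must be one of {BD_MODES}")
        if self.row_alignment not in ROW_ALIGNMENTS:
            raise ValueError(f"row_alignment must be one of {ROW_ALIGNMENTS}")
        if self.angle_mode not in ("abs", "signed"):
            raise ValueError("angle_mode must be 'abs' or 'signed'")
        if self.assignment_mode not in ("optimal", "greedy"):
            raise ValueError("assignment_mode must be 'optimal' or 'greedy'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MatchResult:
    """Final fused correspondence plus the per-feature candidates."""

    final: CorrespondenceSet
    candidates: dict[str, CorrespondenceSet]
    config: RunConfig

    def stage_counts(self) -> dict[str, int]:
        counts = {"unanimous": 0, "majority": 0, "plc": 0}
        for stage in self.final.stages or ():
            counts[stage] += 1
        return counts


def candidate_sets(
    set_a: VectorSet, set_c: VectorSet, config: RunConfig = RunConfig()
) -> dict[str, CorrespondenceSet]:
    """One candidate correspondence per feature (angle, ed, rl)."""
    signed = config.angle_mode == "signed"
    graphs_a = build_all_graphs(set_a, signed_angle=signed)
    graphs_c = build_all_graphs(set_c, signed_angle=signed)
    out: dict[str, CorrespondenceSet] = {}
    for feature in FEATURES:
        sm = build_similarity_matrix(
            graphs_a[feature],
            graphs_c[feature],
            scorer=config.scorer,
            bd_mode=config.bd_mode,
            row_alignment=config.row_alignment,
            bd_max=config.bd_max,
        )
        out[feature] = optimal_assignment(sm, mode=config.assignment_mode)
    return out


def match_vector_sets(
    set_a: VectorSet, set_c: VectorSet, config: RunConfig = RunConfig()
) -> MatchResult:
    """Full pipeline: graphs → similarity → assignment → voting fusion."""
    candidates = candidate_sets(set_a, set_c, config)
    final = run_simva(
        candidates["angle"], candidates["ed"], candidates["rl"], scorer=config.scorer
    )
    return MatchResult(final=final, candidates=candidates, config=config)
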