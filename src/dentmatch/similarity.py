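"""Per-position difference scoring and the normalized dentition similarity.

A recent (PM) dentition is compared against a past (AM) dentition position
by position.  Agreement costs 0 points; a state change that is possible
along the treatment graph costs points proportional to its shortest-path
distance, capped at ``max_position_score``; a change the graph cannot
explain (e.g. an implant reverting to a natural tooth) is an unexplainable
discrepancy and draws the full ``discrepancy_penalty``.  The summed
difference over all 32 positions, divided by the normalization constant and
subtracted from 1, gives a similarity on [0, 1]: identical dentitions score
1.0 and a discrepancy at every position scores exactly 0.0.

Low-similarity candidates are never removed from consideration — the score
only penalizes, it does not filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dentition import (
    FDI_POSITIONS,
    Dentition,
    ToothState,
    TransitionGraph,
)

__all__ = [
    "ScoringParams",
    "SimilarityScore",
    "position_score",
    "similarity_score",
    "position_score_matrix",
]

N_POSITIONS = len(FDI_POSITIONS)


@dataclass(frozen=True)
class ScoringParams:
    """Tunable constants of the difference score.

    Attributes
    ----------
    unit_step_score
        Points per step along the treatment graph.  The default of 3 keeps
        the longest possible escalation below the discrepancy level, so
        impossible transitions always dominate possible ones.
    max_position_score
        Cap on the per-position score (10 points).
    discrepancy_penalty
        Points charged when the recent state is unreachable from the past
        state; equals the cap by default so a discrepancy is maximal.
    normalization_constant
        Denominator turning the summed difference into a [0, 1] score.
        ``None`` materializes to 32 x ``max_position_score`` (= 320).
    """

    unit_step_score: float = 3.0
    max_position_score: float = 10.0
    discrepancy_penalty: float = 10.0
    normalization_constant: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.unit_step_score <= self.max_position_score:
            raise ValueError(
                "unit_step_score must satisfy 0 < unit_step_score "
                f"<= max_position_score, got {self.unit_step_score}"
            )
        if self.discrepancy_penalty < 0:
            raise ValueError("discrepancy_penalty must be non-negative")
        if self.normalization_constant is None:
            object.__setattr__(
                self,
                "normalization_constant",
                N_POSITIONS * self.max_position_score,
            )
        if self.normalization_constant <= 0:
            raise ValueError("normalization_constant must be positive")


@dataclass(frozen=True)
class SimilarityScore:
    """A scored PM-AM comparison with its per-position breakdown."""

    value: float
    difference_total: float
    per_position_scores: Mapping[int, float] = field(repr=False)

    def breakdown(self) -> list[tuple[int, float]]:
        """(fdi_code, points) in canonical position order, for audit export."""
        return [(pos, self.per_position_scores[pos]) for pos in FDI_POSITIONS]


def position_score(
    graph: TransitionGraph,
    params: ScoringParams,
    am_state: ToothState,
    pm_state: ToothState,
) -> float:
    """Difference points for one tooth position.

    0 for identical states; ``unit_step_score`` times the graph distance,
    capped at ``max_position_score``, for a reachable change; the full
    ``discrepancy_penalty`` when the recent state cannot follow the past
    state along the graph.
    """
    am_state, pm_state = ToothState(am_state), ToothState(pm_state)
    if am_state == pm_state:
        return 0.0
    d = graph.distance(am_state, pm_state)
    if d == float("inf"):
        return float(params.discrepancy_penalty)
    return float(min(params.unit_step_score * d, params.max_position_score))


def position_score_matrix(
    graph: TransitionGraph, params: ScoringParams
) -> np.ndarray:
    """6x6 lookup of :func:`position_score` indexed by state enum order.

    Row = AM (past) state, column = PM (recent) state, both in the order of
    iteration over :class:`ToothState`.  Used by the vectorized bulk scorer.
    """
    states = list(ToothState)
    mat = np.empty((len(states), len(states)), dtype=float)
    for i, am in enumerate(states):
        for j, pm in enumerate(states):
            mat[i, j] = position_score(graph, params, am, pm)
    return mat


def similarity_score(
    graph: TransitionGraph,
    params: ScoringParams,
    pm: Dentition,
    am: Dentition,
) -> SimilarityScore:
    """Normalized similarity of a recent dentition to a past dentition.

    Sums :func:`position_score` over all 32 positions and maps the total to
    ``1 - total / normalization_constant``.  The per-position breakdown is
    retained so any score can be explained tooth by tooth.
    """
    per_position = {
        pos: position_score(graph, params, am[pos], pm[pos])
        for pos in FDI_POSITIONS
    }
    total = float(sum(per_position.values()))
    value = 1.0 - total / params.normalization_constant
    return SimilarityScore(
        value=value, difference_total=total, per_position_scores=per_position
    )
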