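"""1:N identification, candidate-group extraction and success rates.

A query (the recent, "postmortem" record) is scored against every record in
the past ("antemortem") database, candidates are sorted by similarity
descending, and competition ranks are assigned: tied scores share a rank
and the next distinct score's rank skips by the tie-block size ("1224"
ranking).  The top-p% candidate group (CG) holds the ceil(p*N) best ranks;
a tie block straddling the boundary is included whole.  The primary success
rate is the fraction of queries whose true past record falls inside the CG;
the literal rank-over-CG-size ratio is kept as a secondary diagnostic.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .dentition import Dentition, ToothState, TransitionGraph
from .similarity import ScoringParams, position_score_matrix, similarity_score

__all__ = [
    "DentitionRecord",
    "MatchResult",
    "EvaluationReport",
    "rank_candidates",
    "extract_candidate_group",
    "candidate_group_size",
    "success_rate",
    "rank_ratio",
    "evaluate_cohort",
    "competition_ranks",
    "score_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_P_LIST: tuple[float, ...] = (0.20, 0.10, 0.05)

_STATE_INDEX = {s: i for i, s in enumerate(ToothState)}


@dataclass(frozen=True)
class DentitionRecord:
    """One radiograph's worth of dentition data for one individual."""

    individual_id: str
    sex: Literal["M", "F"]
    imaging_date: datetime.date
    role: Literal["AM", "PM"]
    dentition: Dentition

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.role not in ("AM", "PM"):
            raise ValueError(f"role must be 'AM' or 'PM', got {self.role!r}")


@dataclass(frozen=True)
class MatchResult:
    """Ranked candidate list for one query.

    ``ranked_candidates`` is sorted by similarity descending, ties ordered
    by ascending candidate id for reproducibility; each entry is
    ``(candidate_id, similarity, competition_rank)``.  ``correct_rank`` is
    the rank of the candidate whose id equals the query id, or ``None``
    for an open-set query absent from the database.
    """

    query_id: str
    ranked_candidates: tuple[tuple[str, float, int], ...]
    correct_rank: int | None
    n_candidates: int

    def correct_similarity(self) -> float | None:
        for cid, score, _rank in self.ranked_candidates:
            if cid == self.query_id:
                return score
        return None

    def in_candidate_group(self, p: float) -> bool | None:
        """Whether the true candidate falls in the top-p% CG (None if open-set)."""
        if self.correct_rank is None:
            return None
        return self.correct_rank <= candidate_group_size(p, self.n_candidates)


@dataclass(frozen=True)
class EvaluationReport:
    """Identification performance for one stratum of a paired cohort."""

    stratum: str
    n_queries: int
    success_rate_by_p: Mapping[float, float]
    rank_ratio_by_p: Mapping[float, float]
    mean_rank_percentile: float


def competition_ranks(scores: Sequence[float]) -> np.ndarray:
    """Competition ("1224") ranks of scores, best = highest score = rank 1.

    Tied scores share the smallest rank of their block; the next distinct
    score's rank equals that rank plus the block size.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("scores must be a non-empty 1-D sequence")
    # rank = 1 + number of strictly better scores
    order = np.argsort(-s, kind="stable")
    ranks = np.empty(s.size, dtype=np.int64)
    rank = 1
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[order[j]] == s[order[i]]:
            j += 1
        ranks[order[i:j]] = rank
        rank += j - i
        i = j
    return ranks


def dentition_code_matrix(dentitions: Iterable[Dentition]) -> np.ndarray:
    """Encode dentitions as an (n, 32) integer matrix of state indices."""
    return np.array(
        [[_STATE_INDEX[s] for s in d.codes()] for d in dentitions],
        dtype=np.int8,
    )


def score_matrix(
    pm_dentitions: Sequence[Dentition],
    am_dentitions: Sequence[Dentition],
    graph: TransitionGraph,
    params: ScoringParams,
) -> np.ndarray:
    """All-pairs similarity, rows = queries (PM), columns = candidates (AM).

    Vectorized equivalent of calling :func:`~dentmatch.similarity.similarity_score`
    for every pair: per-position points come from a 6x6 lookup table and are
    summed over the 32 positions.
    """
    lut = position_score_matrix(graph, params)
    pm = dentition_code_matrix(pm_dentitions)  # (q, 32)
    am = dentition_code_matrix(am_dentitions)  # (n, 32)
    # difference[q, n] = sum over positions of lut[am_state, pm_state]
    diff = lut[am[np.newaxis, :, :], pm[:, np.newaxis, :]].sum(axis=2)
    return 1.0 - diff / params.normalization_constant


def rank_candidates(
    pm: DentitionRecord,
    am_database: Sequence[DentitionRecord],
    graph: TransitionGraph,
    params: ScoringParams,
) -> MatchResult:
    """Score one query against the whole AM database and rank candidates.

    Every database record is scored exactly once; ties share a competition
    rank and are listed in ascending id order.  A query id absent from the
    database is allowed (open-set): ``correct_rank`` is then ``None``.
    """
    if not am_database:
        raise ValueError("AM database must be non-empty")
    scored = [
        (
            rec.individual_id,
            similarity_score(graph, params, pm.dentition, rec.dentition).value,
        )
        for rec in am_database
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    ranks = competition_ranks([score for _, score in scored])
    ranked = tuple(
        (cid, score, int(rank)) for (cid, score), rank in zip(scored, ranks)
    )
    correct_rank = next(
        (rank for cid, _score, rank in ranked if cid == pm.individual_id), None
    )
    return MatchResult(
        query_id=pm.individual_id,
        ranked_candidates=ranked,
        correct_rank=correct_rank,
        n_candidates=len(am_database),
    )


def candidate_group_size(p: float, database_size: int) -> int:
    """Nominal CG size: ceil(p * N)."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if database_size < 1:
        raise ValueError("database_size must be positive")
    return math.ceil(p * database_size)


def extract_candidate_group(
    result: MatchResult, p: float, database_size: int | None = None
) -> set[str]:
    """Ids of the top-p% candidate group.

    Membership is by competition rank <= ceil(p * N), which automatically
    includes a whole tie block whenever the boundary falls inside it (the
    actual CG may then exceed the nominal size; this favors recall and is
    deterministic).
    """
    n = result.n_candidates if database_size is None else database_size
    cg_size = candidate_group_size(p, n)
    return {
        cid for cid, _score, rank in result.ranked_candidates if rank <= cg_size
    }


def success_rate(results: Sequence[MatchResult], p: float) -> float:
    """Percentage of queries whose true candidate lies inside the top-p% CG."""
    if not results:
        raise ValueError("results must be non-empty")
    hits = [r.in_candidate_group(p) for r in results]
    known = [h for h in hits if h is not None]
    if not known:
        raise ValueError("no closed-set queries to evaluate")
    return 100.0 * sum(known) / len(known)


def rank_ratio(results: Sequence[MatchResult], p: float) -> float:
    """Secondary diagnostic: mean 100 * rank / CG size over in-CG queries.

    This is the literal rank-over-group-size reading of the success-rate
    formula; it is reported alongside the primary hit rate, never instead
    of it.  NaN when no query lands in the CG.
    """
    if not results:
        raise ValueError("results must be non-empty")
    ratios = [
        100.0 * r.correct_rank / candidate_group_size(p, r.n_candidates)
        for r in results
        if r.in_candidate_group(p)
    ]
    return float(np.mean(ratios)) if ratios else float("nan")


def _split_pairs(
    cohort: Sequence[DentitionRecord],
) -> tuple[list[DentitionRecord], list[DentitionRecord]]:
    """Split a paired cohort into aligned (PM queries, AM database) lists."""
    ams = {r.individual_id: r for r in cohort if r.role == "AM"}
    pms = {r.individual_id: r for r in cohort if r.role == "PM"}
    if set(ams) != set(pms):
        odd = sorted(set(ams) ^ set(pms))
        raise ValueError(f"cohort is not paired; unpaired ids: {odd[:10]}")
    ids = sorted(ams)
    return [pms[i] for i in ids], [ams[i] for i in ids]


def match_cohort(
    cohort: Sequence[DentitionRecord],
    graph: TransitionGraph,
    params: ScoringParams,
) -> list[MatchResult]:
    """Run every PM query of a paired cohort against the full AM database.

    Uses the vectorized all-pairs scorer; the output is identical to
    calling :func:`rank_candidates` per query.
    """
    pms, ams = _split_pairs(cohort)
    scores = score_matrix(
        [r.dentition for r in pms], [r.dentition for r in ams], graph, params
    )
    am_ids = [r.individual_id for r in ams]
    results = []
    for qi, pm in enumerate(pms):
        row = list(zip(am_ids, scores[qi]))
        row.sort(key=lambda item: (-item[1], item[0]))
        ranks = competition_ranks([score for _, score in row])
        ranked = tuple(
            (cid, float(score), int(rank))
            for (cid, score), rank in zip(row, ranks)
        )
        correct_rank = next(
            rank for cid, _s, rank in ranked if cid == pm.individual_id
        )
        results.append(
            MatchResult(
                query_id=pm.individual_id,
                ranked_candidates=ranked,
                correct_rank=correct_rank,
                n_candidates=len(ams),
            )
        )
    return results


def evaluate_cohort(
    cohort: Sequence[DentitionRecord],
    graph: TransitionGraph,
    params: ScoringParams,
    p_list: Sequence[float] = DEFAULT_P_LIST,
    stratify_by_sex: bool = False,
) -> list[EvaluationReport]:
    """Closed-set identification performance, overall or per sex stratum.

    For sex strata both the queries and the database are restricted to the
    stratum.  An empty stratum is skipped with a warning.
    """
    strata: list[tuple[str, list[DentitionRecord]]] = [("all", list(cohort))]
    if stratify_by_sex:
        for sex in ("M", "F"):
            strata.append(
                (sex, [r for r in cohort if r.sex == sex])
            )
    reports = []
    for name, records in strata:
        if not records:
            logger.warning("stratum %r has no individuals; skipped", name)
            continue
        results = match_cohort(records, graph, params)
        reports.append(
            EvaluationReport(
                stratum=name,
                n_queries=len(results),
                success_rate_by_p={p: success_rate(results, p) for p in p_list},
                rank_ratio_by_p={p: rank_ratio(results, p) for p in p_list},
                mean_rank_percentile=float(
                    np.mean(
                        [100.0 * r.correct_rank / r.n_candidates for r in results]
                    )
                ),
            )
        )
    return reports
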