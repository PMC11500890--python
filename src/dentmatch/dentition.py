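"""Tooth positions, treatment states and the directed state-change graph.

The data model reduces a dental panoramic radiograph to the treatment state
of each of the 32 permanent teeth (FDI two-digit notation, third molars
included).  Every tooth is in exactly one of six states, and over time a
tooth may only move along the directed edges of a treatment-escalation
graph: a natural tooth can be restored, root-treated or lost, but nothing
ever becomes natural again, while a missing-tooth position, a pontic and an
implant are mutually interconvertible.  Reachability and shortest-path
distance on that graph are the primitives every downstream score builds on.
"""

from __future__ import annotations

import enum
import json
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "ToothState",
    "FDI_POSITIONS",
    "UNREACHABLE",
    "TransitionGraph",
    "Dentition",
    "default_transition_graph",
    "is_reachable",
    "state_distance",
    "possible_past_states",
]


class ToothState(str, enum.Enum):
    """The six per-tooth treatment states.

    NATURAL is the pristine, untreated state.  PROSTHESIS covers any direct
    or indirect restoration of a present tooth (filling, inlay, crown).
    ROOT_CANAL marks endodontic treatment.  MISSING, PONTIC (the artificial
    tooth of a fixed bridge) and IMPLANT describe positions where the
    natural tooth is gone.
    """

    NATURAL = "NATURAL"
    PROSTHESIS = "PROSTHESIS"
    ROOT_CANAL = "ROOT_CANAL"
    MISSING = "MISSING"
    PONTIC = "PONTIC"
    IMPLANT = "IMPLANT"

    def __str__(self) -> str:  # keeps CSV cells readable
        return self.value


#: Canonical ordering of the 32 permanent-tooth FDI codes: upper right
#: (18..11), upper left (21..28), lower right (48..41), lower left (31..38).
FDI_POSITIONS: tuple[int, ...] = (
    tuple(range(18, 10, -1))
    + tuple(range(21, 29))
    + tuple(range(48, 40, -1))
    + tuple(range(31, 39))
)

_VALID_POSITIONS = frozenset(FDI_POSITIONS)

#: Sentinel distance for state pairs with no directed path.
UNREACHABLE: float = math.inf

#: Edges of the canonical treatment-escalation graph.
DEFAULT_EDGES: frozenset[tuple[ToothState, ToothState]] = frozenset(
    {
        (ToothState.NATURAL, ToothState.PROSTHESIS),
        (ToothState.NATURAL, ToothState.ROOT_CANAL),
        (ToothState.PROSTHESIS, ToothState.ROOT_CANAL),
        (ToothState.NATURAL, ToothState.MISSING),
        (ToothState.PROSTHESIS, ToothState.MISSING),
        (ToothState.ROOT_CANAL, ToothState.MISSING),
        (ToothState.MISSING, ToothState.PONTIC),
        (ToothState.PONTIC, ToothState.MISSING),
        (ToothState.MISSING, ToothState.IMPLANT),
        (ToothState.IMPLANT, ToothState.MISSING),
        (ToothState.PONTIC, ToothState.IMPLANT),
        (ToothState.IMPLANT, ToothState.PONTIC),
    }
)


def validate_position(fdi_code: int) -> int:
    """Return ``fdi_code`` if it is one of the 32 permanent-tooth FDI codes."""
    if fdi_code not in _VALID_POSITIONS:
        raise ValueError(f"invalid FDI tooth code: {fdi_code!r}")
    return fdi_code


class TransitionGraph:
    """Directed graph over the six tooth states.

    An edge (a, b) means a tooth currently in state ``a`` may next be
    observed in state ``b``.  The node set is always all six states even if
    a state has no edges.  All-pairs shortest-path lengths are precomputed
    at construction, so reachability and distance queries are O(1).

    Parameters
    ----------
    edges
        Iterable of ``(from_state, to_state)`` pairs.  Self-loops are
        rejected: staying in a state is the implicit zero-step transition.
    """

    def __init__(self, edges: Iterable[tuple[ToothState, ToothState]]) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(ToothState)
        for a, b in edges:
            a, b = ToothState(a), ToothState(b)
            if a == b:
                raise ValueError(f"self-loop {a} -> {b} is not a state change")
            g.add_edge(a, b)
        self._graph = g
        self._dist: dict[ToothState, dict[ToothState, int]] = {
            src: dict(lengths)
            for src, lengths in nx.all_pairs_shortest_path_length(g)
        }

    @property
    def edges(self) -> frozenset[tuple[ToothState, ToothState]]:
        return frozenset(self._graph.edges)

    def has_edge(self, past: ToothState, recent: ToothState) -> bool:
        return self._graph.has_edge(ToothState(past), ToothState(recent))

    def successors(self, state: ToothState) -> frozenset[ToothState]:
        return frozenset(self._graph.successors(ToothState(state)))

    def is_reachable(self, past: ToothState, recent: ToothState) -> bool:
        """True iff ``recent`` lies on some directed path from ``past``.

        Reflexive: every state is reachable from itself in zero steps.
        """
        return ToothState(recent) in self._dist[ToothState(past)]

    def distance(self, past: ToothState, recent: ToothState) -> int | float:
        """Shortest directed path length from ``past`` to ``recent``.

        Returns 0 for identical states and :data:`UNREACHABLE` when no
        directed path exists.
        """
        return self._dist[ToothState(past)].get(ToothState(recent), UNREACHABLE)

    def possible_past_states(self, recent: ToothState) -> frozenset[ToothState]:
        """All states from which ``recent`` is reachable (including itself)."""
        recent = ToothState(recent)
        return frozenset(s for s in ToothState if self.is_reachable(s, recent))

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        edge_list = sorted([a.value, b.value] for a, b in self.edges)
        return json.dumps({"edges": edge_list}, indent=2)

    @classmethod
    def from_json(cls, document: str) -> "TransitionGraph":
        payload = json.loads(document)
        return cls((ToothState(a), ToothState(b)) for a, b in payload["edges"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionGraph):
            return NotImplemented
        return self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)

    def __repr__(self) -> str:
        return f"TransitionGraph({len(self.edges)} edges)"


def default_transition_graph() -> TransitionGraph:
    """The canonical treatment-escalation graph.

    Natural teeth may be restored (PROSTHESIS), root-treated (ROOT_CANAL)
    or lost (MISSING); a restored tooth may later need endodontic treatment
    or be lost; a root-treated tooth may be lost; and MISSING, PONTIC and
    IMPLANT are pairwise interconvertible.  NATURAL has in-degree zero —
    no treatment is ever undone.
    """
    return TransitionGraph(DEFAULT_EDGES)


def is_reachable(
    graph: TransitionGraph, past: ToothState, recent: ToothState
) -> bool:
    return graph.is_reachable(past, recent)


def state_distance(
    graph: TransitionGraph, past: ToothState, recent: ToothState
) -> int | float:
    return graph.distance(past, recent)


def possible_past_states(
    graph: TransitionGraph, recent: ToothState
) -> frozenset[ToothState]:
    return graph.possible_past_states(recent)


@dataclass(frozen=True)
class Dentition:
    """The 32-position state vector of one radiograph.

    ``states`` maps every FDI code in :data:`FDI_POSITIONS` to exactly one
    :class:`ToothState`; construction rejects incomplete or over-complete
    mappings and names the offending positions.
    """

    states: Mapping[int, ToothState]

    def __post_init__(self) -> None:
        given = set(self.states)
        missing = _VALID_POSITIONS - given
        extra = given - _VALID_POSITIONS
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"missing positions {sorted(missing)}")
            if extra:
                parts.append(f"invalid positions {sorted(extra)}")
            raise ValueError("incomplete dentition: " + "; ".join(parts))
        normalized = {pos: ToothState(s) for pos, s in self.states.items()}
        object.__setattr__(self, "states", normalized)

    @classmethod
    def uniform(cls, state: ToothState) -> "Dentition":
        """A dentition with every position in the same state."""
        return cls({pos: ToothState(state) for pos in FDI_POSITIONS})

    @classmethod
    def from_codes(cls, codes: Iterable[ToothState | str]) -> "Dentition":
        """Build from 32 state codes in canonical :data:`FDI_POSITIONS` order."""
        codes = [ToothState(c) for c in codes]
        if len(codes) != len(FDI_POSITIONS):
            raise ValueError(
                f"expected {len(FDI_POSITIONS)} state codes, got {len(codes)}"
            )
        return cls(dict(zip(FDI_POSITIONS, codes)))

    def codes(self) -> tuple[ToothState, ...]:
        """State codes in canonical position order."""
        return tuple(self.states[pos] for pos in FDI_POSITIONS)

    def replace(self, fdi_code: int, state: ToothState) -> "Dentition":
        """A copy with one position set to ``state``."""
        validate_position(fdi_code)
        updated = dict(self.states)
        updated[fdi_code] = ToothState(state)
        return Dentition(updated)

    def __getitem__(self, fdi_code: int) -> ToothState:
        return self.states[validate_position(fdi_code)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dentition):
            return NotImplemented
        return self.codes() == other.codes()

    def __hash__(self) -> int:
        return hash(self.codes())
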