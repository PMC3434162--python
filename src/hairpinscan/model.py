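"""CRF topology: 12 sub-models, 3 mature-location paths, and emission scoring.

The state graph mirrors hairpin anatomy.  A background (Non-miRNA) state
with a self transition flanks everything; a hairpin traversal runs through
a left Flanking chain (20 states), one of three duplex paths, and a right
Flanking chain back to the background state.  The three paths encode the
three possible locations of the mature strand in the duplex:

* Mature(5' arm) - Loop - Passenger(3' arm)
* Passenger(5' arm) - Loop - Mature(3' arm)
* Mature(5' arm) - Loop - Mature(3' arm)   (both strands mature)

Mature and Passenger sub-models are chains of 25 states with skip edges
``s -> 25`` for s in 17..24, so a traversal consumes 18-25 positions
(the observed mature-length range).  Loop sub-models are chains of 8
states, each with a self transition (traversals of >= 8 positions).
Every state carries its own emission weight table: one weight per symbol
per dimension (5+5+5+5+5+6+4 = 35 weights per state); the emission score
of a symbol vector is the sum of the seven matching weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .features import DIM_OFFSETS, DIM_SIZES, EMISSION_WIDTH

LABELS = "MPLFN"
ROLE_TO_LABEL = {
    "Mature": "M",
    "Passenger": "P",
    "Loop": "L",
    "Flanking": "F",
    "NonMiRNA": "N",
}


class State(NamedTuple):
    index: int
    submodel: str
    role: str
    label: str
    pos: int  # 1-based position within the sub-model chain


@dataclass(frozen=True)
class ArchConfig:
    """State counts of the sub-models (defaults follow the published design)."""

    duplex_states: int = 25
    loop_states: int = 8
    flank_states: int = 20
    skip_entry: int = 17  # skip edges s -> duplex_states for s in skip_entry..duplex_states-1

    def __post_init__(self) -> None:
        if not 1 <= self.skip_entry <= self.duplex_states:
            raise ValueError("skip_entry must lie within the duplex chain")

    @property
    def duplex_min_len(self) -> int:
        return self.skip_entry + 1

    @property
    def duplex_max_len(self) -> int:
        return self.duplex_states


class GraphError(ValueError):
    pass


class StateGraph:
    """Emitting states, transition edges, and the anchored start/end.

    Transition parameters are ordered: one per edge, then one per start
    attachment, then one per end attachment.
    """

    def __init__(self, states: list[State], edges: list[tuple[int, int]],
                 start_states: list[int], end_states: list[int],
                 s_mirna: set[int], s_5end: set[int],
                 arch: ArchConfig | None = None):
        self.states = states
        self.edges = edges
        self.start_states = list(start_states)
        self.end_states = list(end_states)
        self.s_mirna = set(s_mirna)
        self.s_5end = set(s_5end)
        self.arch = arch
        self._edge_index = {e: i for i, e in enumerate(edges)}
        self._validate()
        self._engine = None

    # -- basic counts ------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_transitions(self) -> int:
        return self.n_edges + len(self.start_states) + len(self.end_states)

    @property
    def n_emission_parameters(self) -> int:
        return self.n_states * EMISSION_WIDTH

    @property
    def n_parameters(self) -> int:
        return self.n_emission_parameters + self.n_transitions

    @property
    def submodels(self) -> dict[str, list[State]]:
        out: dict[str, list[State]] = {}
        for s in self.states:
            out.setdefault(s.submodel, []).append(s)
        return out

    def labels_array(self) -> np.ndarray:
        return np.array([s.label for s in self.states])

    def edge_id(self, u: int, v: int) -> int:
        try:
            return self._edge_index[(u, v)]
        except KeyError:
            raise GraphError(f"no edge {u} -> {v}") from None

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        n = self.n_states
        for u, v in self.edges:
            if not (0 <= u < n and 0 <= v < n):
                raise GraphError(f"edge ({u}, {v}) references unknown state")
        succ: dict[int, list[int]] = {}
        pred: dict[int, list[int]] = {}
        for u, v in self.edges:
            succ.setdefault(u, []).append(v)
            pred.setdefault(v, []).append(u)
        reach = set(self.start_states)
        stack = list(self.start_states)
        while stack:
            u = stack.pop()
            for v in succ.get(u, ()):
                if v not in reach:
                    reach.add(v)
                    stack.append(v)
        coreach = set(self.end_states)
        stack = list(self.end_states)
        while stack:
            v = stack.pop()
            for u in pred.get(v, ()):
                if u not in coreach:
                    coreach.add(u)
                    stack.append(u)
        dead = sorted(set(range(n)) - (reach & coreach))
        if dead:
            names = [f"{self.states[k].submodel}.{self.states[k].pos}" for k in dead]
            raise GraphError(f"unreachable or dead-end states: {names}")

    # -- cached arrays for the forward-backward engine ---------------------
    def engine_arrays(self):
        if self._engine is None:
            e_from = np.array([u for u, _ in self.edges], dtype=np.intp)
            e_to = np.array([v for _, v in self.edges], dtype=np.intp)
            to_order = np.argsort(e_to, kind="stable")
            to_sorted = e_to[to_order]
            to_states, to_offsets = np.unique(to_sorted, return_index=True)
            from_order = np.argsort(e_from, kind="stable")
            from_sorted = e_from[from_order]
            from_states, from_offsets = np.unique(from_sorted, return_index=True)
            self._engine = {
                "e_from": e_from, "e_to": e_to,
                "to_order": to_order, "to_states": to_states, "to_offsets": to_offsets,
                "from_order": from_order, "from_states": from_states,
                "from_offsets": from_offsets,
                "start": np.array(self.start_states, dtype=np.intp),
                "end": np.array(self.end_states, dtype=np.intp),
            }
        return self._engine


def build_state_graph(arch: ArchConfig | None = None) -> StateGraph:
    """Construct the default 12-sub-model topology."""
    arch = arch or ArchConfig()
    states: list[State] = []
    edges: list[tuple[int, int]] = []

    def add_chain(name: str, role: str, n: int) -> list[int]:
        base = len(states)
        for p in range(1, n + 1):
            states.append(State(base + p - 1, name, role, ROLE_TO_LABEL[role], p))
        for p in range(n - 1):
            edges.append((base + p, base + p + 1))
        return list(range(base, base + n))

    nm = add_chain("NonMiRNA", "NonMiRNA", 1)[0]
    edges.append((nm, nm))  # background self transition

    fl_left = add_chain("FlankingLeft", "Flanking", arch.flank_states)
    fl_right = add_chain("FlankingRight", "Flanking", arch.flank_states)

    def add_duplex(name: str, role: str) -> list[int]:
        ids = add_chain(name, role, arch.duplex_states)
        last = ids[-1]
        for s in range(arch.skip_entry, arch.duplex_states - 1):
            edges.append((ids[s - 1], last))  # skip edge s -> final state
        return ids

    def add_loop(name: str) -> list[int]:
        ids = add_chain(name, "Loop", arch.loop_states)
        for k in ids:
            edges.append((k, k))
        return ids

    paths = []
    for pname, first_role, second_role in (
            ("A", "Mature", "Passenger"),
            ("B", "Passenger", "Mature"),
            ("C", "Mature", "Mature")):
        first = add_duplex(f"{first_role}5p{pname}", first_role)
        loop = add_loop(f"Loop{pname}")
        second = add_duplex(f"{second_role}3p{pname}", second_role)
        paths.append((first, loop, second))

    edges.append((nm, fl_left[0]))
    for first, loop, second in paths:
        edges.append((fl_left[-1], first[0]))
        edges.append((first[-1], loop[0]))
        edges.append((loop[-1], second[0]))
        edges.append((second[-1], fl_right[0]))
    edges.append((fl_right[-1], nm))

    s_mirna = {s.index for s in states if s.role != "NonMiRNA"}
    s_5end = {s.index for s in states if s.role == "Mature" and s.pos == 1}
    return StateGraph(states, edges, start_states=[nm], end_states=[nm],
                      s_mirna=s_mirna, s_5end=s_5end, arch=arch)


@dataclass
class ModelParameters:
    """Emission weight tables and transition weights for a state graph.

    The flat parameter vector ``m`` concatenates the emission table
    (row-major over states, then the 35 symbol slots) and the transition
    weights (edges, start attachments, end attachments).
    """

    emission: np.ndarray   # [n_states, EMISSION_WIDTH]
    transition: np.ndarray  # [n_transitions]

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if not (np.isfinite(self.emission).all() and np.isfinite(self.transition).all()):
            raise ValueError("model parameters must be finite")

    @classmethod
    def zeros(cls, graph: StateGraph) -> "ModelParameters":
        return cls(np.zeros((graph.n_states, EMISSION_WIDTH)),
                   np.zeros(graph.n_transitions))

    @property
    def flat(self) -> np.ndarray:
        return np.concatenate([self.emission.ravel(), self.transition])

    @classmethod
    def from_flat(cls, graph: StateGraph, vec: np.ndarray) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        ne = graph.n_emission_parameters
        if vec.size != ne + graph.n_transitions:
            raise ValueError("flat parameter vector has the wrong length")
        return cls(vec[:ne].reshape(graph.n_states, EMISSION_WIDTH),
                   vec[ne:].copy())


def emission_score(params: ModelParameters, state: int,
                   symbol_codes) -> float:
    """Sum of the per-dimension weights of one symbol vector in one state."""
    codes = np.asarray(symbol_codes)
    if codes.shape != (7,):
        raise ValueError("symbol vector must have 7 dimensions")
    total = 0.0
    for d in range(7):
        c = int(codes[d])
        if c >= DIM_SIZES[d]:
            raise ValueError(f"unknown symbol {c} in dimension {d + 1}")
        total += params.emission[state, DIM_OFFSETS[d] + c]
    return float(total)


def path_score(params: ModelParameters, graph: StateGraph,
               state_path: list[int], symbols) -> float:
    """Unnormalized CRF log-potential of one state path over a symbol sequence.

    ``exp(path_score)`` is the path's unnormalized probability.
    """
    codes = symbols.codes if hasattr(symbols, "codes") else np.asarray(symbols)
    if len(state_path) != codes.shape[0]:
        raise ValueError("path length must equal sequence length")
    if not state_path:
        return 0.0
    ne = graph.n_edges
    ns = len(graph.start_states)
    if state_path[0] not in graph.start_states:
        raise GraphError(f"path may not start in state {state_path[0]}")
    if state_path[-1] not in graph.end_states:
        raise GraphError(f"path may not end in state {state_path[-1]}")
    score = params.transition[ne + graph.start_states.index(state_path[0])]
    score += params.transition[ne + ns + graph.end_states.index(state_path[-1])]
    for t, k in enumerate(state_path):
        score += emission_score(params, k, codes[t])
        if t > 0:
            try:
                eid = graph.edge_id(state_path[t - 1], k)
            except GraphError:
                raise GraphError(
                    f"illegal transition {state_path[t - 1]} -> {k} at step {t}"
                ) from None
            score += params.transition[eid]
    return float(score)
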