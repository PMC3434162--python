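"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hairpinscan.model import ModelParameters, State, StateGraph, path_score


# ---------------------------------------------------------------------------
# brute-force CRF oracles (kept independent of the forward-backward engine)
# ---------------------------------------------------------------------------

def enumerate_paths(graph: StateGraph, length: int) -> list[list[int]]:
    """All legal state paths of the given length from start to end anchors."""
    succ: dict[int, list[int]] = {}
    for u, v in graph.edges:
        succ.setdefault(u, []).append(v)
    out: list[list[int]] = []

    def rec(path: list[int]) -> None:
        if len(path) == length:
            if path[-1] in graph.end_states:
                out.append(list(path))
            return
        for v in succ.get(path[-1], ()):
            rec(path + [v])

    for s in graph.start_states:
        rec([s])
    return out


def brute_force_posteriors(params: ModelParameters, graph: StateGraph,
                           codes: np.ndarray, labels: str | None = None):
    """(logZ, per-position per-state posteriors) by explicit path summation.

    With ``labels``, restricts to paths whose state labels match.
    """
    T = codes.shape[0]
    paths = enumerate_paths(graph, T)
    if labels is not None:
        lab = [graph.states[k].label for k in range(graph.n_states)]
        paths = [p for p in paths if all(lab[k] == labels[t]
                                         for t, k in enumerate(p))]
    if not paths:
        return -np.inf, np.zeros((T, graph.n_states))
    scores = np.array([path_score(params, graph, p, codes) for p in paths])
    m = scores.max()
    logZ = m + np.log(np.exp(scores - m).sum())
    post = np.zeros((T, graph.n_states))
    for p, w in zip(paths, np.exp(scores - logZ)):
        for t, k in enumerate(p):
            post[t, k] += w
    return float(logZ), post


def make_toy_graph(labels: str = "MLN", edges=None,
                   start=None, end=None) -> StateGraph:
    """A small generic graph: one state per character of ``labels``."""
    role = {"M": "Mature", "P": "Passenger", "L": "Loop",
            "F": "Flanking", "N": "NonMiRNA"}
    states = [State(i, f"S{i}", role[c], c, 1) for i, c in enumerate(labels)]
    n = len(labels)
    if edges is None:  # fully connected incl. self loops
        edges = [(u, v) for u in range(n) for v in range(n)]
    start = list(range(n)) if start is None else start
    end = list(range(n)) if end is None else end
    s_mirna = {i for i, c in enumerate(labels) if c != "N"}
    s_5end = {i for i, c in enumerate(labels) if c == "M"}
    return StateGraph(states, edges, start, end, s_mirna, s_5end)


def random_toy_instance(rng: np.random.Generator, max_states: int = 6,
                        max_len: int = 8):
    """A random small graph + parameters + symbols (+ feasible labels)."""
    n = int(rng.integers(2, max_states + 1))
    labels = "".join(rng.choice(list("MPLFN"), n))
    if "N" not in labels:
        labels = labels[:-1] + "N"
    # random connected-ish edge set: chain plus random extras and self loops
    edges = {(i, i + 1) for i in range(n - 1)} | {(i, i) for i in range(n)}
    extra = rng.integers(0, n * n, size=n)
    edges |= {(int(e) // n, int(e) % n) for e in extra}
    g = make_toy_graph(labels, sorted(edges))
    T = int(rng.integers(2, max_len + 1))
    codes = rng.integers(0, 4, size=(T, 7)).astype(np.uint8)
    params = ModelParameters.from_flat(g, rng.normal(0.0, 0.7, g.n_parameters))
    paths = enumerate_paths(g, T)
    lab_str = None
    if paths:
        p = paths[int(rng.integers(0, len(paths)))]
        lab_str = "".join(g.states[k].label for k in p)
    return g, params, codes, lab_str


@pytest.fixture(scope="session")
def toy_graph():
    return make_toy_graph("MLN", edges=[(0, 0), (0, 1), (1, 1), (1, 2),
                                        (2, 2), (2, 0)],
                          start=[2], end=[2])


@pytest.fixture(scope="session")
def mini_benchmark():
    """One small seeded end-to-end run shared by several tests."""
    import warnings
    from hairpinscan import evaluation

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluation.synthetic_benchmark(seed=7, genome_length=20_000,
                                              n_hairpins=6, n_decoys=6)
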