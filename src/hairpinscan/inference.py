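"""Posterior decoding: hairpin and mature-5'-end probability tracks.

The forward-backward algorithm yields, for every position ``i``, the
posterior probability ``p[i, k]`` of being generated by state ``k``.  The
hairpin probability is the total posterior mass on states outside the
background sub-model; the mature-5'-end probability is the mass on the
entry states of the Mature sub-models.  Hairpin segments are maximal runs
with hairpin probability above a threshold ``T``, kept when 80 <= length
< 150 bp; 5'-end calls are positions with 5'-end probability above ``T``
(optionally restricted to called segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as ft
from .features import QuantileCodec, ConservationTracks, SymbolSequence
from .model import ModelParameters, StateGraph
from .rna_structure import FoldConfig, compute_pair_probabilities

MIN_SEGMENT = 80
MAX_SEGMENT = 150  # segments of this length or more are discarded

_COMPLEMENT = str.maketrans("ACGTUN", "UGCAAN")


class DecodingError(RuntimeError):
    pass


@dataclass
class PosteriorTracks:
    """Per-position hairpin and mature-5'-end posterior probabilities."""

    p_mi: np.ndarray
    p_5end: np.ndarray
    offset: int = 0
    posteriors: np.ndarray | None = None  # optional [T, K] per-state posteriors


@dataclass
class Segment:
    start: int  # 0-based half-open
    end: int
    score: float  # max hairpin probability within the segment
    strand: str = "+"


@dataclass
class FiveEndCall:
    position: int
    probability: float
    strand: str = "+"


@dataclass
class Prediction:
    segments: list[Segment]
    five_end_calls: list[FiveEndCall]
    tracks: PosteriorTracks
    threshold_hairpin: float
    threshold_5end: float


# ---------------------------------------------------------------------------
# batched log-space forward-backward engine
# ---------------------------------------------------------------------------

def _emission_matrix(params: ModelParameters, codes: np.ndarray) -> np.ndarray:
    """Emission log-scores E[b, t, k] for a batch of symbol code arrays."""
    B, T, _ = codes.shape
    K = params.emission.shape[0]
    E = np.zeros((B, T, K))
    for d in range(7):
        idx = ft.DIM_OFFSETS[d] + codes[:, :, d].astype(np.intp)
        E += params.emission[:, idx].transpose(1, 2, 0)
    return E


def _scatter(B: int, K: int, states: np.ndarray, vals: np.ndarray) -> np.ndarray:
    out = np.full((B, K), -np.inf)
    out[:, states] = vals
    return out


def fb_batch(params: ModelParameters, graph: StateGraph, codes: np.ndarray,
             mask: np.ndarray | None = None, want_counts: bool = False):
    """Forward-backward over a batch of equal-length symbol sequences.

    Parameters
    ----------
    codes
        uint8 array [B, T, 7] of symbol codes.
    mask
        Optional boolean [B, T, K]; False entries forbid a state at a
        position (label-constrained decoding).
    want_counts
        Also accumulate expected transition counts and per-state/symbol
        emission counts (for training gradients).

    Returns
    -------
    dict with ``logZ`` [B], ``post`` [B, T, K] and, if requested,
    ``trans_counts`` [n_transitions] and ``emis_counts`` [K, 35] summed over
    the batch.
    """
    eng = graph.engine_arrays()
    B, T, _ = codes.shape
    K = graph.n_states
    E = _emission_matrix(params, codes)
    if mask is not None:
        E = np.where(mask, E, -np.inf)

    n_edges = graph.n_edges
    w_edges = params.transition[:n_edges]
    w_start = params.transition[n_edges:n_edges + len(graph.start_states)]
    w_end = params.transition[n_edges + len(graph.start_states):]

    to_order, to_states, to_offsets = eng["to_order"], eng["to_states"], eng["to_offsets"]
    from_order = eng["from_order"]
    from_states, from_offsets = eng["from_states"], eng["from_offsets"]
    ef_sorted_to = eng["e_from"][to_order]
    w_sorted_to = w_edges[to_order]
    et_sorted_from = eng["e_to"][from_order]
    w_sorted_from = w_edges[from_order]

    with np.errstate(invalid="ignore"):
        alpha = np.full((B, T, K), -np.inf)
        alpha[:, 0, :] = _scatter(B, K, eng["start"], w_start) + E[:, 0, :]
        for t in range(1, T):
            contrib = alpha[:, t - 1, ef_sorted_to] + w_sorted_to
            red = np.logaddexp.reduceat(contrib, to_offsets, axis=1)
            alpha[:, t, :] = _scatter(B, K, to_states, red) + E[:, t, :]
        logZ = _logsumexp_axis(alpha[:, T - 1, eng["end"]] + w_end)
        if not np.isfinite(logZ).all():
            raise DecodingError("no admissible state path (log-partition is -inf)")

        beta = np.full((B, T, K), -np.inf)
        beta[:, T - 1, :] = _scatter(B, K, eng["end"], np.broadcast_to(w_end, (B, w_end.size)))
        for t in range(T - 2, -1, -1):
            contrib = (w_sorted_from + E[:, t + 1, et_sorted_from]
                       + beta[:, t + 1, et_sorted_from])
            red = np.logaddexp.reduceat(contrib, from_offsets, axis=1)
            beta[:, t, :] = _scatter(B, K, from_states, red)

        post = np.exp(alpha + beta - logZ[:, None, None])
    out = {"logZ": logZ, "post": post}
    if want_counts:
        e_from, e_to = eng["e_from"], eng["e_to"]
        trans_counts = np.zeros(graph.n_transitions)
        with np.errstate(invalid="ignore"):
            for t in range(T - 1):
                ep = np.exp(alpha[:, t, e_from] + w_edges
                            + E[:, t + 1, e_to] + beta[:, t + 1, e_to]
                            - logZ[:, None])
                trans_counts[:n_edges] += ep.sum(axis=0)
        trans_counts[n_edges:n_edges + len(graph.start_states)] = \
            post[:, 0, eng["start"]].sum(axis=0)
        trans_counts[n_edges + len(graph.start_states):] = \
            post[:, T - 1, eng["end"]].sum(axis=0)
        emis_counts = np.zeros((K, ft.EMISSION_WIDTH))
        flat_post = post.reshape(B * T, K)
        for d in range(7):
            sym = codes[:, :, d].reshape(B * T)
            for s in range(ft.DIM_SIZES[d]):
                sel = sym == s
                if sel.any():
                    emis_counts[:, ft.DIM_OFFSETS[d] + s] += flat_post[sel].sum(axis=0)
        out["trans_counts"] = trans_counts
        out["emis_counts"] = emis_counts
    return out


def _logsumexp_axis(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=-1)
    safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        return np.where(
            np.isfinite(m),
            safe + np.log(np.exp(a - safe[..., None]).sum(axis=-1)),
            -np.inf)


def forward_backward(params: ModelParameters, graph: StateGraph,
                     symbols: SymbolSequence) -> tuple[np.ndarray, float]:
    """Per-state posteriors ``p[i, k]`` and the log-partition for one sequence."""
    codes = symbols.codes if hasattr(symbols, "codes") else np.asarray(symbols)
    if codes.shape[0] == 0:
        return np.zeros((0, graph.n_states)), 0.0
    res = fb_batch(params, graph, codes[None, :, :])
    return res["post"][0], float(res["logZ"][0])


# ---------------------------------------------------------------------------
# probability tracks and calling
# ---------------------------------------------------------------------------

def hairpin_probability(posteriors: np.ndarray, graph: StateGraph) -> np.ndarray:
    """P(position in a hairpin) = posterior mass on the hairpin states."""
    idx = np.fromiter(sorted(graph.s_mirna), dtype=np.intp)
    return posteriors[:, idx].sum(axis=1)


def mature_5end_probability(posteriors: np.ndarray, graph: StateGraph) -> np.ndarray:
    """P(position is a mature 5'-end) = mass on the Mature entry states."""
    idx = np.fromiter(sorted(graph.s_5end), dtype=np.intp)
    return posteriors[:, idx].sum(axis=1)


def call_hairpins(p_mi: np.ndarray, T: float, offset: int = 0,
                  min_len: int = MIN_SEGMENT, max_len: int = MAX_SEGMENT,
                  strand: str = "+") -> list[Segment]:
    """Maximal runs with p_mi > T, kept when min_len <= length < max_len."""
    if not 0 < T < 1:
        raise ValueError("threshold T must lie in (0, 1)")
    above = np.asarray(p_mi) > T
    segments: list[Segment] = []
    n = above.size
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if min_len <= j - i < max_len:
                segments.append(Segment(offset + i, offset + j,
                                        float(np.max(p_mi[i:j])), strand))
            i = j
        else:
            i += 1
    return segments


def call_5ends(p_5end: np.ndarray, T: float, segments: list[Segment] | None = None,
               gate: bool = True, offset: int = 0,
               strand: str = "+") -> list[FiveEndCall]:
    """Positions with p_5end > T, optionally gated to called segments."""
    if not 0 < T <= 1:
        raise ValueError("threshold T must lie in (0, 1]")
    pos = np.nonzero(np.asarray(p_5end) > T)[0]
    calls = [FiveEndCall(offset + int(i), float(p_5end[i]), strand) for i in pos]
    if gate and segments is not None:
        spans = [(s.start, s.end) for s in segments]
        calls = [c for c in calls if any(a <= c.position < b for a, b in spans)]
    return calls


# ---------------------------------------------------------------------------
# genome scanning
# ---------------------------------------------------------------------------

@dataclass
class ScannerModel:
    """A self-contained scanner: graph, weights, codec, and fold settings."""

    graph: StateGraph
    params: ModelParameters
    codec: QuantileCodec
    fold_config: FoldConfig = field(default_factory=FoldConfig)
    pair_threshold: float = 0.5


def _window_starts(n: int, window: int, step: int) -> list[int]:
    starts = list(range(0, max(n - window, 0) + 1, step))
    if starts[-1] != n - window and n > window:
        starts.append(n - window)
    return starts


def _stitch_owner(n: int, starts: list[int], window: int) -> np.ndarray:
    """Window index owning each position: the window with the nearest center."""
    centers = np.array([s + window / 2.0 for s in starts])
    pos = np.arange(n)
    return np.argmin(np.abs(pos[:, None] - centers[None, :]), axis=1)


def decode_tracks(model: ScannerModel, symbols: SymbolSequence,
                  window: int = 2000, overlap: int = 400,
                  batch: int = 16) -> PosteriorTracks:
    """Posterior tracks over a long symbol sequence, stitched from windows.

    Each position takes its posterior from the window whose center is
    nearest, which keeps it far from the forced background anchoring at
    window edges.
    """
    n = len(symbols)
    graph, params = model.graph, model.params
    if n <= window:
        post, _ = forward_backward(params, graph, symbols)
        return PosteriorTracks(hairpin_probability(post, graph),
                               mature_5end_probability(post, graph))
    if overlap >= window:
        raise ValueError("window must be longer than overlap")
    step = window - overlap
    starts = _window_starts(n, window, step)
    owner = _stitch_owner(n, starts, window)
    p_mi = np.zeros(n)
    p_5 = np.zeros(n)
    codes = symbols.codes
    for b0 in range(0, len(starts), batch):
        chunk = starts[b0:b0 + batch]
        stack = np.stack([codes[s:s + window] for s in chunk])
        res = fb_batch(params, graph, stack)
        for wi, s in enumerate(chunk):
            sel = np.nonzero(owner[s:s + window] == b0 + wi)[0]
            if sel.size == 0:
                continue
            post_w = res["post"][wi]
            p_mi[s + sel] = hairpin_probability(post_w, graph)[sel]
            p_5[s + sel] = mature_5end_probability(post_w, graph)[sel]
    return PosteriorTracks(p_mi, p_5)


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def scan_genome(model: ScannerModel, sequence: str,
                tracks: ConservationTracks | None,
                window: int = 2000, overlap: int = 400, T: float = 0.5,
                T_5end: float | None = None, gate: bool = True,
                both_strands: bool = False) -> Prediction:
    """Fold, featurize, decode, and call hairpins over a genomic sequence.

    The sequence is folded under the model's span constraint, encoded with
    the model's codec, decoded in overlapping windows, and the stitched
    probability tracks are thresholded into hairpin segments and mature
    5'-end calls.  With ``both_strands`` the reverse complement is scanned
    as well and its calls are mapped back to forward coordinates.
    """
    if window < 300 or overlap < 1:
        raise ValueError("window must be >= 300 and overlap positive")
    T_5end = T if T_5end is None else T_5end
    n = len(sequence)

    def one_strand(seq: str, trk: ConservationTracks | None, strand: str):
        bpm = compute_pair_probabilities(seq, model.fold_config)
        raw = ft.build_raw_features(seq, trk, bpm, model.pair_threshold)
        sym = ft.encode(raw, model.codec)
        pt = decode_tracks(model, sym, window, overlap)
        segs = call_hairpins(pt.p_mi, T, strand=strand)
        calls = call_5ends(pt.p_5end, T_5end, segs, gate=gate, strand=strand)
        return pt, segs, calls

    pt, segs, calls = one_strand(sequence, tracks, "+")
    if both_strands:
        rtr = tracks.reverse() if tracks is not None else None
        _, rsegs, rcalls = one_strand(reverse_complement(sequence), rtr, "-")
        for s in rsegs:
            s.start, s.end = n - s.end, n - s.start
        for c in rcalls:
            c.position = n - 1 - c.position
        segs += rsegs
        calls += rcalls
    return Prediction(segs, calls, pt, T, T_5end)
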