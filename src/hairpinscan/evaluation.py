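"""Metrics, cross-validation harness, feature profiling, and the synthetic
end-to-end benchmark.

Detection accuracy is measured by sensitivity ``TP/(TP+FN)``, positive
predictive value ``TP/(TP+FP)``, and their harmonic mean (F-score).
Mature-5'-end accuracy is evaluated within hairpin intervals only, with an
optional positional tolerance (a call within +/- tolerance nt of a true
5'-end is a true positive; each truth site is matched at most once,
nearest call first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import features as ft
from . import inference, simulate, training
from .features import ConservationTracks
from .inference import ScannerModel, Segment, scan_genome
from .model import build_state_graph
from .rna_structure import FoldConfig, compute_pair_probabilities
from .training import LabeledExample, TrainingConfig, select_penalty


@dataclass
class Metrics:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def ppv(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def f_score(self) -> float | None:
        s, p = self.sensitivity, self.ppv
        if s is None or p is None:
            return None
        return 2 * s * p / (s + p) if s + p else 0.0

    @property
    def undefined(self) -> dict[str, bool]:
        return {"sensitivity": self.sensitivity is None,
                "ppv": self.ppv is None,
                "f_score": self.f_score is None}


@dataclass
class EvalReport:
    per_threshold: list[dict] = field(default_factory=list)
    ranking: list[tuple[int, int]] = field(default_factory=list)
    five_end: dict[int, Metrics] = field(default_factory=dict)
    operating_point: dict | None = None


def confusion_metrics(predicted, positives, negatives=None) -> Metrics:
    """Confusion counts over site sets.

    Predicted sites in the positive set are TP; in the negative set, FP
    (when no negative set is given, every non-positive prediction is FP);
    positives never predicted are FN.  Sites in neither set are ignored.
    """
    predicted, positives = set(predicted), set(positives)
    tp = len(predicted & positives)
    if negatives is None:
        fp = len(predicted - positives)
    else:
        fp = len(predicted & set(negatives))
    fn = len(positives - predicted)
    return Metrics(tp, fp, fn)


def five_end_accuracy(calls, truth_ends, hairpin_intervals,
                      tolerance: int = 0) -> Metrics:
    """Tolerance-windowed accuracy of mature 5'-end calls.

    Only calls inside hairpin intervals are classified (positions outside
    hairpins are neither positive nor negative sites).  A call within
    ``tolerance`` nt of an unmatched truth site is a TP (nearest pairs
    matched first, each truth site used once); other in-hairpin calls are
    FP; unmatched truth sites are FN.
    """
    if tolerance not in (0, 1, 2):
        raise ValueError("tolerance must be 0, 1, or 2")
    positions = sorted({c.position if hasattr(c, "position") else int(c)
                        for c in calls})
    inside = [p for p in positions
              if any(a <= p < b for a, b in hairpin_intervals)]
    truth = sorted(set(int(t) for t in truth_ends))
    pairs = sorted(
        ((abs(p - t), p, t) for p in inside for t in truth
         if abs(p - t) <= tolerance))
    used_calls: set[int] = set()
    used_truth: set[int] = set()
    tp = 0
    for _, p, t in pairs:
        if p in used_calls or t in used_truth:
            continue
        used_calls.add(p)
        used_truth.add(t)
        tp += 1
    fp = len(inside) - tp
    fn = len(truth) - tp
    return Metrics(tp, fp, fn)


def ranking_curve(segments: list[Segment], truth_intervals,
                  min_overlap: int = 1) -> list[tuple[int, int]]:
    """Cumulative distinct truth hairpins among the top-N scored segments."""
    ordered = sorted(segments, key=lambda s: (-s.score, s.start))
    hit_truth: set[int] = set()
    curve = []
    for n, seg in enumerate(ordered, start=1):
        for ti, (a, b) in enumerate(truth_intervals):
            if min(seg.end, b) - max(seg.start, a) >= min_overlap:
                hit_truth.add(ti)
        curve.append((n, len(hit_truth)))
    return curve


def segment_detection(segments: list[Segment], truth_intervals,
                      min_overlap: int = 1) -> Metrics:
    """Segment-level detection: a truth hairpin is detected when some
    segment overlaps it by ``min_overlap`` nt; segments overlapping no truth
    are false positives."""
    detected: set[int] = set()
    fp = 0
    for seg in segments:
        hit = False
        for ti, (a, b) in enumerate(truth_intervals):
            if min(seg.end, b) - max(seg.start, a) >= min_overlap:
                detected.add(ti)
                hit = True
        fp += int(not hit)
    tp = len(detected)
    fn = len(truth_intervals) - tp
    return Metrics(tp, fp, fn)


def profile_features(raws, anchors, left: int = 30, right: int = 30,
                     dims=(0, 3, 4)) -> dict:
    """Position-wise mean and median of raw feature dimensions around anchors.

    ``raws`` are RawFeatureSequence objects, ``anchors`` the anchor position
    within each (e.g. duplex 5' start or mature 5'-end).  Returns, per
    requested dimension index, arrays over relative positions
    ``-left..right``.
    """
    offsets = np.arange(-left, right + 1)
    out = {"offsets": offsets}
    for d in dims:
        cols = []
        for raw, anchor in zip(raws, anchors):
            vals = np.full(offsets.size, np.nan)
            for oi, off in enumerate(offsets):
                p = anchor + off
                if 0 <= p < len(raw):
                    vals[oi] = raw.values[p, d]
            cols.append(vals)
        stack = np.vstack(cols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[d] = {"mean": np.nanmean(stack, axis=0),
                      "median": np.nanmedian(stack, axis=0)}
    return out


# ---------------------------------------------------------------------------
# example construction shared by the harnesses
# ---------------------------------------------------------------------------

def featurize_genome(bundle: simulate.SyntheticBundle,
                     fold_config: FoldConfig | None = None,
                     pair_threshold: float = 0.5) -> ft.RawFeatureSequence:
    fold_config = fold_config or FoldConfig()
    bpm = compute_pair_probabilities(bundle.sequence, fold_config)
    return ft.build_raw_features(bundle.sequence, bundle.tracks, bpm,
                                 pair_threshold)


def build_examples(bundle: simulate.SyntheticBundle,
                   raw: ft.RawFeatureSequence,
                   codec: ft.QuantileCodec,
                   n_negatives: int, seed: int,
                   window: int = 200) -> tuple[list[LabeledExample],
                                               list[LabeledExample]]:
    """Standardized positive and background training windows for a bundle."""
    sym = ft.encode(raw, codec)
    positives = []
    pos_windows = []
    for ri, rec in enumerate(bundle.truth):
        s, e, labels = simulate.standardize_window(bundle, rec, window)
        positives.append(LabeledExample(sym.codes[s:e], labels, f"hp{ri}"))
        pos_windows.append((s, e))
    n_low = n_negatives - n_negatives // 2
    n_high = n_negatives // 2
    regions = simulate.sample_background_regions(
        bundle.tracks, n_low, n_high, window=window, seed=seed,
        exclude=[(r.start, r.end) for r in bundle.truth])
    negatives = [LabeledExample(sym.codes[s:e], "N" * (e - s), f"bg{i}_{kind}")
                 for i, (s, e, kind) in enumerate(regions)]
    return positives, negatives


def fit_codec_on_hairpins(raw: ft.RawFeatureSequence,
                          windows: list[tuple[int, int]]) -> ft.QuantileCodec:
    """Quantile codec fitted on the raw feature values of hairpin windows."""
    pooled = [np.concatenate([raw.values[s:e, d] for s, e in windows])
              for d in range(6)]
    return ft.fit_quantile_codec(pooled)


# ---------------------------------------------------------------------------
# cross validation
# ---------------------------------------------------------------------------

@dataclass
class CVItem:
    example: LabeledExample
    truth_span: tuple[int, int] | None  # span of the hairpin within the window
    fold: object
    family: object = None


def cross_validate(items: list[CVItem], graph=None,
                   config: TrainingConfig | None = None) -> dict:
    """Leave-one-fold-out evaluation with family-aware exclusion.

    For each fold: training examples are those from other folds whose
    family does not occur in the held-out fold; the penalty is selected on
    an internal split; the held-out examples are decoded and scored.
    """
    graph = graph or build_state_graph()
    config = config or TrainingConfig()
    folds = sorted({it.fold for it in items}, key=str)
    reports = {}
    for fold in folds:
        test = [it for it in items if it.fold == fold]
        test_families = {it.family for it in test if it.family is not None}
        train = [it for it in items
                 if it.fold != fold and (it.family is None
                                         or it.family not in test_families)]
        train_pos = [it.example for it in train if it.truth_span is not None]
        train_neg = [it.example for it in train if it.truth_span is None]
        if not train_pos:
            warnings.warn(f"fold {fold!r}: no training positives; skipped")
            continue
        c_best, params, sel_report = select_penalty(train_pos, train_neg,
                                                    graph, config)
        ev = training.evaluate_examples(params, graph,
                                        [it.example for it in test],
                                        config.threshold_grid)
        reports[fold] = {"selected_c": c_best, "selection": sel_report,
                         "evaluation": ev}
    return reports


# ---------------------------------------------------------------------------
# end-to-end synthetic benchmark
# ---------------------------------------------------------------------------

def synthetic_benchmark(seed: int, genome_length: int = 100_000,
                        n_hairpins: int = 20, n_decoys: int = 20,
                        spec: simulate.HairpinSpec | None = None,
                        config: TrainingConfig | None = None,
                        fold_config: FoldConfig | None = None,
                        window: int = 2000, overlap: int = 400) -> dict:
    """Simulate, train (with penalty selection), scan, and evaluate.

    A synthetic genome with planted hairpins and conserved decoy blocks is
    generated from ``seed``; the scanner is trained on standardized 200-bp
    windows with penalty selection over the default grid, the genome is
    scanned, the hairpin threshold is swept for the maximum F-score, and
    detection plus 5'-end accuracy are reported.  Fully deterministic for
    a fixed seed.
    """
    spec = spec or simulate.HairpinSpec()
    config = config or TrainingConfig(rng_seed=seed)
    fold_config = fold_config or FoldConfig()

    bundle = simulate.generate_genome(n_hairpins, genome_length, spec,
                                      seed=seed, n_decoys=n_decoys)
    raw = featurize_genome(bundle, fold_config)
    pos_windows = [simulate.standardize_window(bundle, rec)[:2]
                   for rec in bundle.truth]
    codec = fit_codec_on_hairpins(raw, pos_windows)
    positives, negatives = build_examples(bundle, raw, codec,
                                          n_negatives=n_hairpins, seed=seed)
    graph = build_state_graph()
    c_best, params, sel_report = select_penalty(positives, negatives, graph,
                                                config)
    model = ScannerModel(graph, params, codec, fold_config)

    sym = ft.encode(raw, codec)
    tracks = inference.decode_tracks(model, sym, window=window, overlap=overlap)
    truth_spans = [(r.start, r.end) for r in bundle.truth]
    truth_ends = [p for r in bundle.truth for p in r.five_ends]

    per_t = []
    for T in config.threshold_grid:
        segs = inference.call_hairpins(tracks.p_mi, T)
        m = segment_detection(segs, truth_spans)
        f = m.f_score if m.f_score is not None else 0.0
        per_t.append((f, float(T), segs, m))
    best_f, best_T, best_segs, best_m = max(per_t, key=lambda r: (r[0], -r[1]))

    calls = inference.call_5ends(tracks.p_5end, best_T, best_segs, gate=True)
    five = {tol: five_end_accuracy(calls, truth_ends, truth_spans, tol)
            for tol in (0, 1, 2)}
    detected = [ti for ti, (a, b) in enumerate(truth_spans)
                if any(s.start < b and s.end > a for s in best_segs)]
    with_call = 0
    for ti in detected:
        rec = bundle.truth[ti]
        ends = rec.five_ends
        if any(min(abs(c.position - t) for t in ends) <= 2 for c in calls
               if rec.start <= c.position < rec.end):
            with_call += 1
    frac_5end = with_call / len(detected) if detected else 0.0

    curve = ranking_curve(best_segs, truth_spans)
    return {
        "seed": seed,
        "genome_length": genome_length,
        "n_hairpins": n_hairpins,
        "n_decoys": n_decoys,
        "selected_c": c_best,
        "selection_report": sel_report,
        "best_threshold": best_T,
        "best_f": best_f,
        "sensitivity": best_m.sensitivity,
        "ppv": best_m.ppv,
        "n_segments": len(best_segs),
        "segments": [(s.start, s.end, s.score) for s in best_segs],
        "five_end_calls": [(c.position, c.probability) for c in calls],
        "five_end_metrics": {tol: {"tp": m.tp, "fp": m.fp, "fn": m.fn,
                                   "sensitivity": m.sensitivity, "ppv": m.ppv}
                             for tol, m in five.items()},
        "frac_detected_with_5end_within_2nt": frac_5end,
        "ranking_curve": curve,
        "per_threshold": [{"threshold": t, "f": f, "tp": m.tp, "fp": m.fp,
                           "fn": m.fn} for f, t, _, m in per_t],
    }
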