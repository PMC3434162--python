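"""Training: label-constrained conditional likelihood with a Gaussian prior.

The model is trained discriminatively.  For a labeled example (symbol
sequence ``x``, label sequence ``y`` over {M, P, L, F, N}) the objective is

    L(m) = log Z_constrained(x, y; m) - log Z(x; m)

where ``Z_constrained`` sums the Boltzmann weights of all state paths whose
per-position labels match ``y`` (several states share a label, so the
labeling does not pin down a unique path), and ``Z`` sums over all legal
paths.  The total objective over examples is penalized with a Gaussian
prior ``- sum_j m_j^2 / (2 c)``, so larger ``c`` means weaker shrinkage.
All parameters start at zero and are fitted with L-BFGS.

The penalty constant ``c`` is chosen from a small grid by maximum F-score
on a held-out split, mirroring how the scanner is used: fit on one group,
decode the other, sweep the probability threshold, keep the best F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import inference
from .inference import call_hairpins, fb_batch
from .model import ModelParameters, StateGraph

LABEL_SET = "MPLFN"


class LabelError(ValueError):
    pass


@dataclass
class LabeledExample:
    """A symbol sequence with per-position labels in {M, P, L, F, N}."""

    symbols: object              # SymbolSequence or uint8 array [T, 7]
    labels: str
    example_id: str = ""

    def __post_init__(self) -> None:
        self.codes = (self.symbols.codes if hasattr(self.symbols, "codes")
                      else np.asarray(self.symbols, dtype=np.uint8))
        if len(self.labels) != self.codes.shape[0]:
            raise LabelError(
                f"{self.example_id or 'example'}: {len(self.labels)} labels for "
                f"{self.codes.shape[0]} positions")
        bad = set(self.labels) - set(LABEL_SET)
        if bad:
            raise LabelError(f"unknown labels {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.codes.shape[0])


@dataclass
class TrainingConfig:
    penalty_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 50.0, 100.0)
    split_fraction: float = 0.8
    rng_seed: int = 0
    grad_tol: float = 1e-5
    max_iter: int = 500
    threshold_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 2))

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if not self.penalty_grid:
            raise ValueError("penalty grid must be non-empty")


def _label_runs(labels: str) -> list[tuple[str, int, int]]:
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((labels[i], i, j))
        i = j
    return runs


def validate_labels(example: LabeledExample, graph: StateGraph) -> list[str]:
    """Structural compatibility of a label string with the state graph.

    Returns a list of human-readable violations (empty when compatible).
    """
    arch = graph.arch
    problems = []
    labels = example.labels
    if labels and labels[0] != "N":
        problems.append("sequence must start in the background (N) label")
    if labels and labels[-1] != "N":
        problems.append("sequence must end in the background (N) label")
    for lab, a, b in _label_runs(labels):
        ln = b - a
        if lab in "MP" and arch is not None and not (
                arch.duplex_min_len <= ln <= arch.duplex_max_len):
            problems.append(f"{lab}-run [{a},{b}) has length {ln}, expected "
                            f"{arch.duplex_min_len}-{arch.duplex_max_len}")
        if lab == "F" and arch is not None and ln != arch.flank_states:
            problems.append(f"F-run [{a},{b}) has length {ln}, expected "
                            f"{arch.flank_states}")
        if lab == "L" and arch is not None and ln < arch.loop_states:
            problems.append(f"L-run [{a},{b}) has length {ln}, expected >= "
                            f"{arch.loop_states}")
    return problems


def _label_mask(examples: list[LabeledExample], graph: StateGraph) -> np.ndarray:
    state_labels = graph.labels_array()
    B = len(examples)
    T = len(examples[0])
    K = graph.n_states
    mask = np.zeros((B, T, K), dtype=bool)
    for b, ex in enumerate(examples):
        lab = np.frombuffer(ex.labels.encode(), dtype="S1").astype("U1")
        mask[b] = lab[:, None] == state_labels[None, :]
    return mask


def _first_infeasible_position(example: LabeledExample, graph: StateGraph) -> int:
    """Index of the first position at which no labeled path can continue."""
    eng = graph.engine_arrays()
    state_labels = graph.labels_array()
    ok = np.zeros(graph.n_states, dtype=bool)
    allowed0 = state_labels == example.labels[0]
    ok[eng["start"]] = True
    ok &= allowed0
    if not ok.any():
        return 0
    succ: dict[int, list[int]] = {}
    for u, v in graph.edges:
        succ.setdefault(u, []).append(v)
    for t in range(1, len(example)):
        nxt = np.zeros_like(ok)
        for u in np.nonzero(ok)[0]:
            for v in succ.get(int(u), ()):
                nxt[v] = True
        nxt &= state_labels == example.labels[t]
        if not nxt.any():
            return t
        ok = nxt
    return len(example) - 1


def _batched(examples: list[LabeledExample], graph: StateGraph,
             params: ModelParameters, want_counts: bool):
    """Constrained and full passes over examples, grouped by length."""
    groups: dict[int, list[LabeledExample]] = {}
    for ex in examples:
        groups.setdefault(len(ex), []).append(ex)
    value = 0.0
    counts_diff = None
    for exs in groups.values():
        codes = np.stack([ex.codes for ex in exs])
        mask = _label_mask(exs, graph)
        try:
            cons = fb_batch(params, graph, codes, mask=mask, want_counts=want_counts)
        except inference.DecodingError:
            for ex in exs:
                try:
                    fb_batch(params, graph, ex.codes[None], mask=_label_mask([ex], graph))
                except inference.DecodingError:
                    pos = _first_infeasible_position(ex, graph)
                    raise LabelError(
                        f"{ex.example_id or 'example'}: labels admit no state "
                        f"path (first infeasible position {pos})") from None
            raise
        full = fb_batch(params, graph, codes, want_counts=want_counts)
        value += float((cons["logZ"] - full["logZ"]).sum())
        if want_counts:
            d_em = cons["emis_counts"] - full["emis_counts"]
            d_tr = cons["trans_counts"] - full["trans_counts"]
            if counts_diff is None:
                counts_diff = [d_em, d_tr]
            else:
                counts_diff[0] += d_em
                counts_diff[1] += d_tr
    return value, counts_diff


def constrained_log_likelihood(params: ModelParameters, example: LabeledExample,
                               graph: StateGraph) -> tuple[float, np.ndarray]:
    """Log-likelihood of the labels and its gradient in the flat parameterization.

    value = log Z_constrained - log Z <= 0; gradient = E_constrained[counts]
    - E_full[counts].
    """
    value, (d_em, d_tr) = _batched([example], graph, params, want_counts=True)
    return value, np.concatenate([d_em.ravel(), d_tr])


def penalized_objective(params_flat: np.ndarray, examples: list[LabeledExample],
                        c: float, graph: StateGraph) -> tuple[float, np.ndarray]:
    """Sum of example log-likelihoods minus the Gaussian prior sum m^2/(2c)."""
    if c <= 0:
        raise ValueError("penalty constant c must be positive")
    params = ModelParameters.from_flat(graph, params_flat)
    value, (d_em, d_tr) = _batched(examples, graph, params, want_counts=True)
    grad = np.concatenate([d_em.ravel(), d_tr])
    value -= float(params_flat @ params_flat) / (2.0 * c)
    grad = grad - params_flat / c
    return value, grad


@dataclass
class FitResult:
    params: ModelParameters
    converged: bool
    n_iterations: int
    objective_trace: list[float] = field(default_factory=list)


def fit(examples: list[LabeledExample], c: float, config: TrainingConfig | None,
        graph: StateGraph, trace_objective: bool = False) -> FitResult:
    """Maximize the penalized objective from the all-zero start with L-BFGS."""
    config = config or TrainingConfig()
    for ex in examples:
        problems = validate_labels(ex, graph)
        if problems:
            warnings.warn(f"{ex.example_id or 'example'}: " + "; ".join(problems))
    trace: list[float] = []

    def neg(m):
        v, g = penalized_objective(m, examples, c, graph)
        return -v, -g

    def cb(m):
        v, _ = penalized_objective(m, examples, c, graph)
        trace.append(v)

    x0 = np.zeros(graph.n_parameters)
    res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                   callback=cb if trace_objective else None,
                   options={"maxiter": config.max_iter, "gtol": config.grad_tol,
                            "ftol": 1e-10})
    if not res.success and "ITERATIONS" in str(res.message).upper():
        warnings.warn(f"optimizer stopped before convergence: {res.message}")
    return FitResult(ModelParameters.from_flat(graph, res.x),
                     bool(res.success), int(res.nit), trace)


def _hairpin_span(labels: str) -> tuple[int, int] | None:
    """Half-open span of the non-background labels, if any."""
    idx = [i for i, l in enumerate(labels) if l != "N"]
    if not idx:
        return None
    return idx[0], idx[-1] + 1


def evaluate_examples(params: ModelParameters, graph: StateGraph,
                      examples: list[LabeledExample],
                      thresholds) -> dict:
    """Decode examples and sweep the hairpin threshold; report per-T metrics.

    A labeled-hairpin example counts as detected when a called segment
    overlaps its true span; called segments without such an overlap count
    as false positives.
    """
    spans = [_hairpin_span(ex.labels) for ex in examples]
    codes = np.stack([ex.codes for ex in examples])
    res = fb_batch(params, graph, codes)
    p_mi = np.stack([inference.hairpin_probability(res["post"][b], graph)
                     for b in range(len(examples))])
    per_t = []
    for T in thresholds:
        tp = fp = fn = 0
        for b, span in enumerate(spans):
            segs = call_hairpins(p_mi[b], T)
            hit = False
            for s in segs:
                if span is not None and s.start < span[1] and s.end > span[0]:
                    hit = True
                else:
                    fp += 1
            if span is not None:
                tp += int(hit)
                fn += int(not hit)
        sens = tp / (tp + fn) if tp + fn else None
        ppv = tp / (tp + fp) if tp + fp else None
        f = (2 * sens * ppv / (sens + ppv)
             if sens and ppv and sens + ppv > 0 else 0.0)
        per_t.append({"threshold": float(T), "tp": tp, "fp": fp, "fn": fn,
                      "sensitivity": sens, "ppv": ppv, "f": f})
    best = max(per_t, key=lambda r: r["f"])
    return {"per_threshold": per_t, "best": best}


def select_penalty(positives: list[LabeledExample], negatives: list[LabeledExample],
                   graph: StateGraph, config: TrainingConfig | None = None
                   ) -> tuple[float, ModelParameters, dict]:
    """Choose the penalty constant by held-out maximum F-score.

    The positives are split (by the configured seed) into a training group
    of ``split_fraction`` plus an equal number of negatives, and a
    validation group of the remainder; each grid value of ``c`` is fitted
    on the training group and scored on the validation group by the
    maximum F-score over the threshold grid.
    """
    config = config or TrainingConfig()
    rng = np.random.default_rng(config.rng_seed)
    n_pos = len(positives)
    n_train = int(round(config.split_fraction * n_pos))
    if n_train == 0 or n_train == n_pos:
        raise ValueError("split leaves an empty training or validation group")
    order = rng.permutation(n_pos)
    train_pos = [positives[i] for i in order[:n_train]]
    valid_pos = [positives[i] for i in order[n_train:]]
    neg_order = rng.permutation(len(negatives))
    n_neg_train = min(n_train, len(negatives))
    train_neg = [negatives[i] for i in neg_order[:n_neg_train]]
    valid_neg = [negatives[i] for i in neg_order[n_neg_train:]]
    if not valid_pos:
        raise ValueError("empty validation group")
    report = {"per_c": [], "split": {"n_train_pos": len(train_pos),
                                     "n_train_neg": len(train_neg),
                                     "n_valid_pos": len(valid_pos),
                                     "n_valid_neg": len(valid_neg)}}
    best = None
    for c in config.penalty_grid:
        fitres = fit(train_pos + train_neg, c, config, graph)
        ev = evaluate_examples(fitres.params, graph, valid_pos + valid_neg,
                               config.threshold_grid)
        entry = {"c": float(c), "max_f": ev["best"]["f"],
                 "best_threshold": ev["best"]["threshold"],
                 "n_iterations": fitres.n_iterations}
        report["per_c"].append(entry)
        if best is None or entry["max_f"] > best[0]:
            best = (entry["max_f"], float(c), fitres.params)
    report["selected_c"] = best[1]
    report["selected_max_f"] = best[0]
    return best[1], best[2], report
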