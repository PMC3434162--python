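"""Label-constrained likelihood, gradients, fitting, and penalty selection."""

import warnings

import numpy as np
import pytest

from hairpinscan import training
from hairpinscan.model import ModelParameters, build_state_graph
from hairpinscan.training import (
    LabeledExample,
    LabelError,
    TrainingConfig,
    constrained_log_likelihood,
    fit,
    penalized_objective,
    select_penalty,
)

from conftest import brute_force_posteriors, enumerate_paths, make_toy_graph


def toy():
    return make_toy_graph("MLN", edges=[(0, 0), (0, 1), (1, 1), (1, 2),
                                        (2, 2), (2, 0)],
                          start=[2], end=[2])


def random_example(g, rng, T=5):
    codes = rng.integers(0, 4, size=(T, 7)).astype(np.uint8)
    paths = enumerate_paths(g, T)
    p = paths[int(rng.integers(0, len(paths)))]
    labels = "".join(g.states[k].label for k in p)
    return LabeledExample(codes, labels)


class TestConstrainedLikelihood:
    def test_zero_parameters_count_paths(self):
        g = toy()
        rng = np.random.default_rng(0)
        ex = random_example(g, rng, T=5)
        params = ModelParameters.zeros(g)
        v, _ = constrained_log_likelihood(params, ex, g)
        paths = enumerate_paths(g, 5)
        lab = [g.states[k].label for k in range(g.n_states)]
        consistent = [p for p in paths
                      if all(lab[k] == ex.labels[t] for t, k in enumerate(p))]
        assert v == pytest.approx(np.log(len(consistent)) - np.log(len(paths)),
                                  abs=1e-12)

    def test_value_matches_enumeration(self):
        g = toy()
        rng = np.random.default_rng(1)
        for _ in range(5):
            ex = random_example(g, rng, T=6)
            params = ModelParameters.from_flat(
                g, rng.normal(0, 0.8, g.n_parameters))
            v, _ = constrained_log_likelihood(params, ex, g)
            lz_all, _ = brute_force_posteriors(params, g, ex.codes)
            lz_cons, _ = brute_force_posteriors(params, g, ex.codes, ex.labels)
            assert v == pytest.approx(lz_cons - lz_all, abs=1e-9)

    def test_value_is_never_positive(self):
        g = toy()
        rng = np.random.default_rng(2)
        for _ in range(10):
            ex = random_example(g, rng, T=4)
            params = ModelParameters.from_flat(
                g, rng.normal(0, 1.0, g.n_parameters))
            v, _ = constrained_log_likelihood(params, ex, g)
            assert v <= 1e-12

    def test_gradient_matches_central_differences(self):
        g = toy()
        rng = np.random.default_rng(3)
        ex = random_example(g, rng, T=5)
        params = ModelParameters.from_flat(g, rng.normal(0, 0.5, g.n_parameters))
        v, grad = constrained_log_likelihood(params, ex, g)
        h = 1e-5
        idx = rng.choice(grad.size, 30, replace=False)
        for i in idx:
            m = params.flat
            mp, mm = m.copy(), m.copy()
            mp[i] += h
            mm[i] -= h
            vp, _ = constrained_log_likelihood(
                ModelParameters.from_flat(g, mp), ex, g)
            vm, _ = constrained_log_likelihood(
                ModelParameters.from_flat(g, mm), ex, g)
            num = (vp - vm) / (2 * h)
            assert abs(num - grad[i]) < 1e-4 * (1 + abs(num))

    def test_infeasible_labels_name_first_position(self):
        g = make_toy_graph("MLN", edges=[(0, 1), (1, 2), (2, 2), (2, 0)],
                           start=[2], end=[2])
        # after N the graph can go to M but never straight to L
        ex = LabeledExample(np.zeros((4, 7), dtype=np.uint8), "NLLN")
        params = ModelParameters.zeros(g)
        with pytest.raises(LabelError, match="position 1"):
            constrained_log_likelihood(params, ex, g)

    def test_gradient_conservation_identity(self):
        # summed over the symbols of one dimension, emission gradients for a
        # state equal (expected constrained visits - expected total visits)
        g = toy()
        rng = np.random.default_rng(4)
        ex = random_example(g, rng, T=6)
        params = ModelParameters.from_flat(g, rng.normal(0, 0.6, g.n_parameters))
        _, grad = constrained_log_likelihood(params, ex, g)
        from hairpinscan.features import DIM_OFFSETS, DIM_SIZES, EMISSION_WIDTH
        em = grad[:g.n_emission_parameters].reshape(g.n_states, EMISSION_WIDTH)
        _, post_all = brute_force_posteriors(params, g, ex.codes)
        _, post_cons = brute_force_posteriors(params, g, ex.codes, ex.labels)
        visits = (post_cons - post_all).sum(axis=0)
        for d in range(7):
            sl = slice(DIM_OFFSETS[d], DIM_OFFSETS[d] + DIM_SIZES[d])
            assert np.allclose(em[:, sl].sum(axis=1), visits, atol=1e-9)


class TestPenalizedObjective:
    def test_zero_parameters_have_zero_penalty(self):
        g = toy()
        rng = np.random.default_rng(5)
        ex = random_example(g, rng)
        m0 = np.zeros(g.n_parameters)
        v_pen, _ = penalized_objective(m0, [ex], 10.0, g)
        v_raw, _ = constrained_log_likelihood(ModelParameters.zeros(g), ex, g)
        assert v_pen == pytest.approx(v_raw)

    def test_doubling_parameters_quadruples_penalty(self):
        g = toy()
        rng = np.random.default_rng(6)
        ex = random_example(g, rng)
        m = rng.normal(0, 0.3, g.n_parameters)
        c = 5.0

        def penalty(mv):
            v_pen, _ = penalized_objective(mv, [ex], c, g)
            v_raw, _ = constrained_log_likelihood(
                ModelParameters.from_flat(g, mv), ex, g)
            return v_raw - v_pen

        assert penalty(2 * m) == pytest.approx(4 * penalty(m), rel=1e-9)

    def test_gradient_includes_shrinkage_term(self):
        g = toy()
        rng = np.random.default_rng(7)
        ex = random_example(g, rng)
        m = rng.normal(0, 0.3, g.n_parameters)
        c = 2.0
        _, g_pen = penalized_objective(m, [ex], c, g)
        _, g_raw = constrained_log_likelihood(
            ModelParameters.from_flat(g, m), ex, g)
        assert np.allclose(g_pen, g_raw - m / c)

    def test_concave_along_random_segments(self):
        g = toy()
        rng = np.random.default_rng(8)
        exs = [random_example(g, rng) for _ in range(3)]
        for _ in range(5):
            a = rng.normal(0, 0.5, g.n_parameters)
            b = rng.normal(0, 0.5, g.n_parameters)
            va, _ = penalized_objective(a, exs, 10.0, g)
            vb, _ = penalized_objective(b, exs, 10.0, g)
            vm, _ = penalized_objective((a + b) / 2, exs, 10.0, g)
            assert vm >= (va + vb) / 2 - 1e-8


class TestFit:
    def _toy_training_data(self, rng, n=12, T=8):
        """Two-class toy data with a planted symbol bias."""
        g = toy()
        examples = []
        for i in range(n):
            positive = i % 2 == 0
            if positive:
                labels = "N" + "M" * (T - 3) + "LN"
                codes = rng.integers(0, 2, size=(T, 7)).astype(np.uint8)
            else:
                labels = "N" * T
                codes = rng.integers(2, 4, size=(T, 7)).astype(np.uint8)
            examples.append(LabeledExample(codes, labels, f"ex{i}"))
        return g, examples

    def test_fit_separates_biased_classes(self):
        rng = np.random.default_rng(9)
        g, examples = self._toy_training_data(rng)
        res = fit(examples, c=10.0, config=TrainingConfig(max_iter=100),
                  graph=g)
        from hairpinscan.inference import forward_backward, hairpin_probability
        correct = 0
        for ex in examples:
            post, _ = forward_backward(res.params, g, ex.codes)
            p_mi = hairpin_probability(post, g).mean()
            predicted_pos = p_mi > 0.5
            correct += int(predicted_pos == (ex.labels.count("M") > 0))
        assert correct >= 10  # far above the 50% chance level

    def test_objective_trace_is_non_decreasing(self):
        rng = np.random.default_rng(10)
        g, examples = self._toy_training_data(rng, n=6)
        res = fit(examples, c=10.0, config=TrainingConfig(max_iter=40),
                  graph=g, trace_objective=True)
        trace = np.array(res.objective_trace)
        assert trace.size > 2
        assert np.all(np.diff(trace) >= -1e-8)

    def test_refit_is_bit_identical(self):
        rng = np.random.default_rng(11)
        g, examples = self._toy_training_data(rng, n=6)
        cfg = TrainingConfig(max_iter=30)
        a = fit(examples, 10.0, cfg, g).params
        b = fit(examples, 10.0, cfg, g).params
        assert np.array_equal(a.flat, b.flat)

    def test_weaker_penalty_allows_larger_parameters(self):
        rng = np.random.default_rng(12)
        g, examples = self._toy_training_data(rng, n=8)
        small = fit(examples, 0.1, TrainingConfig(max_iter=60), g).params
        large = fit(examples, 100.0, TrainingConfig(max_iter=60), g).params
        assert np.linalg.norm(large.flat) >= np.linalg.norm(small.flat)


class TestParameterRecovery:
    def test_fitted_model_reproduces_labeling_log_odds(self):
        """Labels sampled from a known CRF; refitting recovers the log-odds
        between competing labelings.

        At 2000 training positions individual log-odds carry unavoidable
        sampling noise, so recovery is asserted in aggregate: regressing
        fitted on true log-odds over random (input, labeling-pair) probes
        must give a slope within 10% of 1 and near-perfect correlation.
        """
        from hairpinscan.model import path_score

        g = make_toy_graph("MN", edges=[(0, 0), (0, 1), (1, 0), (1, 1)],
                           start=[1], end=[1])
        rng = np.random.default_rng(13)
        true = ModelParameters.from_flat(g, rng.normal(0, 0.8, g.n_parameters))
        T, n_examples = 4, 500  # 2000 positions in total
        paths = enumerate_paths(g, T)
        lab = [g.states[k].label for k in range(g.n_states)]
        examples = []
        for _ in range(n_examples):
            codes = rng.integers(0, 2, size=(T, 7)).astype(np.uint8)
            scores = np.array([path_score(true, g, p, codes) for p in paths])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            p = paths[int(rng.choice(len(paths), p=w))]
            examples.append(LabeledExample(codes,
                                           "".join(lab[k] for k in p)))
        fitted = fit(examples, c=1000.0, config=TrainingConfig(max_iter=300),
                     graph=g).params

        def log_odds(params, codes, y1, y2):
            lz1, _ = brute_force_posteriors(params, g, codes, y1)
            lz2, _ = brute_force_posteriors(params, g, codes, y2)
            return lz1 - lz2

        rng2 = np.random.default_rng(14)
        lo_true, lo_fit = [], []
        for _ in range(100):
            codes = rng2.integers(0, 2, size=(T, 7)).astype(np.uint8)
            p1, p2 = rng2.choice(len(paths), 2, replace=False)
            y1 = "".join(lab[k] for k in paths[p1])
            y2 = "".join(lab[k] for k in paths[p2])
            if y1 == y2:
                continue
            lo_true.append(log_odds(true, codes, y1, y2))
            lo_fit.append(log_odds(fitted, codes, y1, y2))
        lo_true = np.array(lo_true)
        lo_fit = np.array(lo_fit)
        slope = (lo_true @ lo_fit) / (lo_true @ lo_true)
        assert abs(slope - 1.0) <= 0.10
        assert np.corrcoef(lo_true, lo_fit)[0, 1] >= 0.99


class TestSelectPenalty:
    def test_default_grid_matches_published_values(self):
        assert TrainingConfig().penalty_grid == (0.1, 1.0, 10.0, 50.0, 100.0)

    def test_f_score_of_equal_sens_and_ppv(self):
        from hairpinscan.evaluation import Metrics
        m = Metrics(tp=1, fp=1, fn=1)
        assert m.sensitivity == m.ppv == 0.5
        assert m.f_score == pytest.approx(0.5)

    def test_selection_runs_and_reports(self, mini_benchmark):
        rep = mini_benchmark["selection_report"]
        assert {e["c"] for e in rep["per_c"]} == {0.1, 1.0, 10.0, 50.0, 100.0}
        assert rep["selected_c"] in {0.1, 1.0, 10.0, 50.0, 100.0}
        assert rep["split"]["n_train_pos"] == rep["split"]["n_train_neg"]

    def test_split_errors_without_enough_examples(self):
        g = toy()
        ex = LabeledExample(np.zeros((4, 7), dtype=np.uint8), "NNNN")
        with pytest.raises(ValueError):
            select_penalty([ex], [ex], g, TrainingConfig())


class TestLabelValidation:
    def test_structurally_incompatible_runs_are_reported(self):
        g = build_state_graph()
        labels = ("N" * 30 + "F" * 20 + "M" * 10 + "L" * 10 + "P" * 22
                  + "F" * 20 + "N" * 88)
        ex = LabeledExample(np.zeros((200, 7), dtype=np.uint8), labels)
        problems = training.validate_labels(ex, g)
        assert any("M-run" in p for p in problems)

    def test_wrong_flank_length_is_reported(self):
        g = build_state_graph()
        labels = ("N" * 30 + "F" * 19 + "M" * 22 + "L" * 10 + "P" * 22
                  + "F" * 20 + "N" * 77)
        ex = LabeledExample(np.zeros((200, 7), dtype=np.uint8), labels)
        problems = training.validate_labels(ex, g)
        assert any("F-run" in p for p in problems)

    def test_valid_labels_pass(self):
        g = build_state_graph()
        labels = ("N" * 30 + "F" * 20 + "M" * 22 + "L" * 10 + "P" * 22
                  + "F" * 20 + "N" * 76)
        ex = LabeledExample(np.zeros((200, 7), dtype=np.uint8), labels)
        assert training.validate_labels(ex, g) == []
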