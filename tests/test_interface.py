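"""File formats, model serialization, configuration, and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from hairpinscan import interface
from hairpinscan.cli import main as cli_main
from hairpinscan.features import QuantileCodec
from hairpinscan.inference import (
    FiveEndCall,
    PosteriorTracks,
    Prediction,
    ScannerModel,
    Segment,
)
from hairpinscan.model import ModelParameters, build_state_graph
from hairpinscan.rna_structure import FoldConfig


class TestFasta:
    def test_single_record_round_trip(self, tmp_path):
        p = tmp_path / "x.fa"
        interface.write_fasta(p, {"chr1": "ACGTACGT"})
        assert interface.read_fasta(p) == {"chr1": "ACGTACGT"}

    def test_multi_record_order_preserved(self, tmp_path):
        p = tmp_path / "x.fa"
        interface.write_fasta(p, {"b": "AAAA", "a": "CCCC", "m": "GGGG"})
        assert list(interface.read_fasta(p)) == ["b", "a", "m"]

    def test_crlf_input_accepted(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_bytes(b">s1\r\nACGT\r\nACGT\r\n")
        assert interface.read_fasta(p) == {"s1": "ACGTACGT"}

    def test_lowercase_is_upfolded(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">s\nacgu\n")
        assert interface.read_fasta(p)["s"] == "ACGU"

    def test_duplicate_ids_are_an_error(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">s\nAA\n>s\nCC\n")
        with pytest.raises(interface.FormatError, match="duplicate"):
            interface.read_fasta(p)


class TestTracks:
    def test_bedgraph_assigns_half_open_intervals(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t3\t0.5\nchr1\t3\t5\t0.75\n")
        arr = interface.read_track(p, 6)
        assert arr[:3].tolist() == [0.5, 0.5, 0.5]
        assert arr[3:5].tolist() == [0.75, 0.75]
        assert np.isnan(arr[5])

    def test_wiggle_start_is_one_based(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chr1 start=1 step=1\n0.1\n0.2\n0.3\n")
        arr = interface.read_track(p, 5)
        assert arr[0] == pytest.approx(0.1)
        assert arr[2] == pytest.approx(0.3)
        assert np.isnan(arr[3])

    def test_overlapping_intervals_last_wins_with_warning(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t4\t0.1\nchr1\t2\t4\t0.9\n")
        with pytest.warns(UserWarning, match="last wins"):
            arr = interface.read_track(p, 4)
        assert arr.tolist() == [0.1, 0.1, 0.9, 0.9]

    def test_out_of_range_interval_reports_line(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t2\t0.1\nchr1\t5\t20\t0.2\n")
        with pytest.raises(interface.FormatError, match=":2"):
            interface.read_track(p, 10)

    def test_bedgraph_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = np.round(rng.random(40), 3)
        p = tmp_path / "t.bedgraph"
        interface.write_bedgraph(p, "chr1", vals)
        back = interface.read_track(p, 40)
        assert np.allclose(back, vals, atol=1e-6)


class TestPredictions:
    def _prediction(self):
        tracks = PosteriorTracks(np.linspace(0, 1, 20), np.zeros(20))
        return Prediction(
            segments=[Segment(2, 10, 0.9), Segment(12, 18, 0.4, "-")],
            five_end_calls=[FiveEndCall(4, 0.7)],
            tracks=tracks, threshold_hairpin=0.5, threshold_5end=0.5)

    def test_bed6_round_trip(self, tmp_path):
        pred = self._prediction()
        seg_p, call_p = tmp_path / "s.bed", tmp_path / "c.bed"
        interface.write_predictions(pred, "chr9", seg_p, call_p)
        segs = interface.read_bed6(seg_p)
        assert [(s, e) for _, s, e, *_ in segs] == [(2, 10), (12, 18)]
        assert segs[0][4] == 900  # score = 1000 * max probability
        assert segs[1][5] == "-"
        calls = interface.read_bed6(call_p)
        assert calls[0][1:3] == (4, 5)

    def test_empty_prediction_writes_header_only(self, tmp_path):
        pred = Prediction([], [], PosteriorTracks(np.zeros(5), np.zeros(5)),
                          0.5, 0.5)
        seg_p, call_p = tmp_path / "s.bed", tmp_path / "c.bed"
        interface.write_predictions(pred, "chr1", seg_p, call_p)
        assert interface.read_bed6(seg_p) == []
        assert seg_p.read_text().startswith("track")


class TestModelSerialization:
    def test_model_json_round_trip(self, tmp_path):
        graph = build_state_graph()
        rng = np.random.default_rng(1)
        params = ModelParameters.from_flat(
            graph, rng.normal(size=graph.n_parameters))
        codec = QuantileCodec(np.sort(rng.random((6, 4)), axis=1))
        model = ScannerModel(graph, params, codec,
                             FoldConfig(max_span=90), pair_threshold=0.4)
        p = tmp_path / "model.json"
        interface.save_model(model, p)
        back = interface.load_model(p)
        assert np.array_equal(back.params.emission, params.emission)
        assert np.array_equal(back.params.transition, params.transition)
        assert np.array_equal(back.codec.boundaries, codec.boundaries)
        assert back.fold_config.max_span == 90
        assert back.pair_threshold == 0.4
        assert back.graph.n_states == graph.n_states

    def test_unsupported_schema_is_an_error(self, tmp_path):
        p = tmp_path / "model.json"
        p.write_text(json.dumps({"schema_version": 99}))
        with pytest.raises(interface.FormatError, match="schema"):
            interface.load_model(p)


class TestLabelsAndConfig:
    def test_label_bed_reader(self, tmp_path):
        p = tmp_path / "labels.bed"
        p.write_text("chr1\t0\t3\tN\nchr1\t3\t5\tM\nchr1\t5\t8\tL\n")
        assert interface.read_labels(p, 10) == "NNNMMLLLNN"

    def test_config_json_load_and_missing_path(self, tmp_path):
        cfg_p = tmp_path / "run.json"
        cfg_p.write_text(json.dumps({"window": 1500, "threshold": 0.3}))
        cfg = interface.RunConfig.load(cfg_p)
        assert cfg.window == 1500
        assert cfg.threshold == 0.3
        cfg_p.write_text(json.dumps({"fasta": str(tmp_path / "missing.fa")}))
        with pytest.raises(FileNotFoundError):
            interface.RunConfig.load(cfg_p)

    def test_config_toml_load(self, tmp_path):
        cfg_p = tmp_path / "run.toml"
        cfg_p.write_text('window = 900\noverlap = 300\nseed = 5\n')
        cfg = interface.RunConfig.load(cfg_p)
        assert (cfg.window, cfg.overlap, cfg.seed) == (900, 300, 5)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            interface.RunConfig(threshold=1.5)


class TestMafReader:
    def test_pairwise_blocks_parse(self, tmp_path):
        p = tmp_path / "aln.maf"
        p.write_text(
            "##maf version=1\n"
            "a score=10.0\n"
            "s target.chr1 2 4 + 10 ACGU\n"
            "s other.chr5  0 4 + 20 ACGA\n\n")
        blocks = interface.read_maf(p)
        assert len(blocks) == 1
        assert blocks[0][0].annotations["start"] == 2


class TestCli:
    def test_scan_help_exits_zero(self):
        result = CliRunner().invoke(cli_main, ["scan", "--help"])
        assert result.exit_code == 0

    def test_unknown_flag_is_nonzero(self):
        result = CliRunner().invoke(cli_main, ["scan", "--no-such-flag"])
        assert result.exit_code != 0

    def test_missing_model_file_is_nonzero(self, tmp_path):
        fa = tmp_path / "g.fa"
        interface.write_fasta(fa, {"chr1": "ACGT" * 100})
        result = CliRunner().invoke(cli_main, [
            "scan", str(fa), "--model", str(tmp_path / "absent.json"),
            "--phastcons", str(fa), "--phylop", str(fa)])
        assert result.exit_code != 0

    def test_full_pipeline_smoke(self, tmp_path):
        """simulate -> train -> scan -> eval all exit zero."""
        runner = CliRunner()
        prefix = str(tmp_path / "syn")
        r = runner.invoke(cli_main, [
            "simulate", "--seed", "5", "--n-hairpins", "4",
            "--length", "12000", "--out-prefix", prefix])
        assert r.exit_code == 0, r.output
        fa = f"{prefix}.fa"
        r = runner.invoke(cli_main, [
            "train", fa,
            "--phastcons", f"{prefix}.phastcons.bedgraph",
            "--phylop", f"{prefix}.phylop.bedgraph",
            "--labels", f"{prefix}.truth.bed",
            "--penalty-grid", "10", "--max-iter", "60",
            "--model-out", str(tmp_path / "model.json"),
            "--report-out", str(tmp_path / "report.json")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "scan", fa, "--model", str(tmp_path / "model.json"),
            "--phastcons", f"{prefix}.phastcons.bedgraph",
            "--phylop", f"{prefix}.phylop.bedgraph",
            "--threshold", "0.5",
            "--out-prefix", str(tmp_path / "scan")])
        assert r.exit_code == 0, r.output
        name = "synthetic_seed5"
        r = runner.invoke(cli_main, [
            "eval", str(tmp_path / f"scan.{name}.segments.bed"),
            f"{prefix}.truth.bed", "--out", str(tmp_path / "eval.json")])
        assert r.exit_code == 0, r.output
        rep = json.loads((tmp_path / "eval.json").read_text())
        assert {"tp", "fp", "fn"} <= set(rep)
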