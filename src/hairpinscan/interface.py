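"""File formats and configuration: the only module that touches disk.

Coordinate convention on disk is 0-based half-open everywhere (BED and
bedGraph native); fixed-step wiggle input (1-based) is converted at read
time.  Model files bundle the state graph configuration, the quantile
codec, the fold configuration, and all weights, so a model file is
self-contained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

from .features import ConservationTracks, QuantileCodec
from .inference import FiveEndCall, Prediction, ScannerModel, Segment
from .model import ArchConfig, ModelParameters, build_state_graph
from .rna_structure import FoldConfig

MODEL_SCHEMA_VERSION = 1


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# sequence and track readers
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Ordered mapping id -> uppercase sequence; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_track(path, length: int, chrom: str | None = None) -> np.ndarray:
    """Dense per-position array from bedGraph or fixed-step wiggle.

    Uncovered positions are NaN (missing).  bedGraph intervals are 0-based
    half-open; fixed-step wiggle starts are 1-based and converted.
    """
    arr = np.full(length, np.nan)
    mode = "bedgraph"
    step = span = 1
    pos = 0
    cur_chrom = None
    warned_overlap = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                cur_chrom = fields.get("chrom")
                pos = int(fields["start"]) - 1  # wiggle is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                mode = "wiggle"
                continue
            if mode == "wiggle":
                if chrom is not None and cur_chrom not in (None, chrom):
                    continue
                if pos < 0 or pos + span > length:
                    raise FormatError(f"{path}:{ln}: wiggle position "
                                      f"{pos + 1} out of range")
                arr[pos:pos + span] = float(line)
                pos += step
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln}: expected 4 bedGraph columns")
            c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom is not None and c != chrom:
                continue
            if s < 0 or e > length or s >= e:
                raise FormatError(f"{path}:{ln}: interval [{s}, {e}) out of "
                                  f"range for length {length}")
            if not warned_overlap and np.isfinite(arr[s:e]).any():
                warnings.warn(f"{path}:{ln}: overlapping intervals; last wins")
                warned_overlap = True
            arr[s:e] = v
    return arr


def read_tracks(phastcons_path, phylop_path, length: int,
                chrom: str | None = None) -> ConservationTracks:
    return ConservationTracks(read_track(phastcons_path, length, chrom),
                              read_track(phylop_path, length, chrom))


def write_bedgraph(path, chrom: str, values: np.ndarray, digits: int = 6) -> None:
    """Run-length-compressed 4-column bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        n = values.size
        i = 0
        while i < n:
            j = i
            v = round(float(values[i]), digits)
            while j < n and round(float(values[j]), digits) == v:
                j += 1
            fh.write(f"{chrom}\t{i}\t{j}\t{v:g}\n")
            i = j


def read_maf(path) -> list:
    """Pairwise alignment blocks from a MAF file."""
    try:
        return list(AlignIO.parse(str(path), "maf"))
    except ValueError as exc:
        raise FormatError(f"malformed MAF file {path}: {exc}") from exc


def read_labels(path, length: int, chrom: str | None = None) -> str:
    """Label string from a BED-like file (chrom, start, end, label)."""
    labels = np.full(length, "N")
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 columns")
            c, s, e, lab = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if chrom is not None and c != chrom:
                continue
            if not 0 <= s < e <= length:
                raise FormatError(f"{path}:{ln}: interval out of range")
            labels[s:e] = lab[0]
    return "".join(labels)


# ---------------------------------------------------------------------------
# prediction writers
# ---------------------------------------------------------------------------

def write_predictions(prediction: Prediction, chrom: str, segments_path,
                      calls_path, p_mi_path=None, p_5end_path=None) -> None:
    """Segments and 5'-end calls as BED6; probability tracks as bedGraph."""
    with open(segments_path, "w") as fh:
        fh.write('track name=hairpin_segments\n')
        for i, s in enumerate(prediction.segments):
            score = int(round(1000 * s.score))
            fh.write(f"{chrom}\t{s.start}\t{s.end}\thairpin_{i}\t{score}\t{s.strand}\n")
    with open(calls_path, "w") as fh:
        fh.write('track name=mature_5end_calls\n')
        for i, c in enumerate(prediction.five_end_calls):
            score = int(round(1000 * c.probability))
            fh.write(f"{chrom}\t{c.position}\t{c.position + 1}\t"
                     f"five_end_{i}\t{score}\t{c.strand}\n")
    if p_mi_path is not None:
        write_bedgraph(p_mi_path, chrom, prediction.tracks.p_mi)
    if p_5end_path is not None:
        write_bedgraph(p_5end_path, chrom, prediction.tracks.p_5end)


def read_bed6(path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            c, s, e, name, score, strand = line.split("\t")[:6]
            out.append((c, int(s), int(e), name, int(score), strand))
    return out


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def model_to_json(model: ScannerModel) -> dict:
    arch = model.graph.arch or ArchConfig()
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "arch": {"duplex_states": arch.duplex_states,
                 "loop_states": arch.loop_states,
                 "flank_states": arch.flank_states,
                 "skip_entry": arch.skip_entry},
        "fold": {"max_span": model.fold_config.max_span,
                 "min_loop": model.fold_config.min_loop,
                 "energy_model": model.fold_config.energy_model,
                 "temperature_scale": model.fold_config.temperature_scale},
        "pair_threshold": model.pair_threshold,
        "codec": model.codec.to_json(),
        "emission": model.params.emission.tolist(),
        "transition": model.params.transition.tolist(),
    }


def model_from_json(obj: dict) -> ScannerModel:
    if obj.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise FormatError("unsupported model schema version")
    graph = build_state_graph(ArchConfig(**obj["arch"]))
    params = ModelParameters(np.asarray(obj["emission"]),
                             np.asarray(obj["transition"]))
    return ScannerModel(graph, params, QuantileCodec.from_json(obj["codec"]),
                        FoldConfig(**obj["fold"]), float(obj["pair_threshold"]))


def save_model(model: ScannerModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_json(model), fh)


def load_model(path) -> ScannerModel:
    with open(path) as fh:
        return model_from_json(json.load(fh))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    fasta: str | None = None
    phastcons: str | None = None
    phylop: str | None = None
    labels: str | None = None
    model: str | None = None
    window: int = 2000
    overlap: int = 400
    threshold: float = 0.5
    threshold_5end: float | None = None
    seed: int = 0
    both_strands: bool = False
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in (self.threshold, self.threshold_5end):
            if t is not None and not 0 < t < 1:
                raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib
            obj = tomllib.loads(path.read_text())
        else:
            obj = json.loads(path.read_text())
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in obj.items() if k in known}
        extras = {k: v for k, v in obj.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extras = extras
        for attr in ("fasta", "phastcons", "phylop", "labels", "model"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} path {p!r} does not exist")
        return cfg
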