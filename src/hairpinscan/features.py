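"""Per-position 7-dimensional feature vectors and their symbol encoding.

The seven dimensions of the feature vector at genomic position ``i`` are:

1. conservation score (PhastCons-like, in [0, 1]) at ``i``
2. the same score at ``i - 20``
3. the same score at ``i + 20``
4. a per-column conservation score (PhyloP-like) at ``i``
5. base-pair potential: max over partners j of the pair probability p(i, j)
6. base-pair distance: signed offset ``j* - i`` to the most probable
   partner when the potential passes a threshold, else ``-inf``
7. the nucleotide at ``i``

Dimensions 1-6 are discretized into symbols A-E at the 20/40/60/80th
percentiles of the training values (nearest-rank convention; a value equal
to a boundary belongs to the lower symbol).  Dimension 6 additionally maps
``-inf`` to "F".  Dimension 7 maps A,U,G,C to A,B,C,D.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .rna_structure import BasePairMatrix

DIM_SIZES = (5, 5, 5, 5, 5, 6, 4)
DIM_OFFSETS = tuple(int(x) for x in np.concatenate([[0], np.cumsum(DIM_SIZES)[:-1]]))
EMISSION_WIDTH = int(sum(DIM_SIZES))  # 35
SYMBOLS = "ABCDEF"
NUC_TO_CODE = {"A": 0, "U": 1, "T": 1, "G": 2, "C": 3}
SHIFT = 20  # offset used by dimensions 2 and 3


class CoordinateError(ValueError):
    """Raised when sequence and track coordinate ranges disagree."""


@dataclass
class ConservationTracks:
    """Dense per-base conservation tracks; NaN marks missing positions."""

    phastcons: np.ndarray
    phylop: np.ndarray

    def __post_init__(self) -> None:
        self.phastcons = np.asarray(self.phastcons, dtype=float)
        self.phylop = np.asarray(self.phylop, dtype=float)
        if self.phastcons.shape != self.phylop.shape:
            raise CoordinateError("phastcons and phylop tracks differ in length")
        finite = self.phastcons[np.isfinite(self.phastcons)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("phastcons values must lie in [0, 1]")

    @property
    def length(self) -> int:
        return int(self.phastcons.size)

    def reverse(self) -> "ConservationTracks":
        return ConservationTracks(self.phastcons[::-1].copy(), self.phylop[::-1].copy())


@dataclass
class RawFeatureSequence:
    """Continuous feature vectors: ``values[t, d]`` for d1..d6 plus nucleotides."""

    values: np.ndarray          # [T, 6]; only column 5 (d6) may be -inf
    nuc_codes: np.ndarray       # [T] uint8 in 0..3
    n_mask: np.ndarray          # [T] bool, True where the input base was N
    offset: int = 0

    def __len__(self) -> int:
        return int(self.values.shape[0])


@dataclass
class SymbolSequence:
    """Discretized features: ``codes[t, d]`` is the 0-based symbol index."""

    codes: np.ndarray  # [T, 7] uint8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        for d, size in enumerate(DIM_SIZES):
            if self.codes.size and self.codes[:, d].max(initial=0) >= size:
                raise ValueError(f"symbol out of range in dimension {d + 1}")

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    def strings(self) -> list[str]:
        """Per-position 7-letter symbol strings such as 'EBEEBCA'."""
        return ["".join(SYMBOLS[c] for c in row) for row in self.codes]


def _fill_nearest(arr: np.ndarray) -> np.ndarray:
    """Replace NaNs by the nearest finite value (whole-NaN tracks become 0)."""
    arr = np.asarray(arr, dtype=float).copy()
    bad = ~np.isfinite(arr)
    if not bad.any():
        return arr
    if bad.all():
        warnings.warn("conservation track entirely missing; substituting 0")
        return np.zeros_like(arr)
    idx = np.arange(arr.size)
    good = idx[~bad]
    nearest = good[np.clip(np.searchsorted(good, idx[bad]), 0, good.size - 1)]
    prev = good[np.clip(np.searchsorted(good, idx[bad]) - 1, 0, good.size - 1)]
    pick = np.where(np.abs(nearest - idx[bad]) <= np.abs(idx[bad] - prev), nearest, prev)
    arr[bad] = arr[pick]
    return arr


def build_raw_features(sequence: str, tracks: ConservationTracks | None,
                       bpm: BasePairMatrix, pair_threshold: float = 0.5,
                       offset: int = 0) -> RawFeatureSequence:
    """Assemble the continuous 7-dimensional feature vectors.

    ``pair_threshold`` controls when a position counts as paired for the
    base-pair distance (d6); below it d6 is ``-inf``.
    """
    n = len(sequence)
    if tracks is None:
        warnings.warn("no conservation tracks supplied; substituting 0")
        tracks = ConservationTracks(np.zeros(n), np.zeros(n))
    if tracks.length != n or bpm.length != n:
        raise CoordinateError(
            f"coordinate mismatch: sequence {n} nt, tracks {tracks.length}, "
            f"pair matrix {bpm.length}")
    phast = _fill_nearest(tracks.phastcons)
    phylop = _fill_nearest(tracks.phylop)
    idx = np.arange(n)
    up = np.clip(idx - SHIFT, 0, max(n - 1, 0))
    down = np.clip(idx + SHIFT, 0, max(n - 1, 0))
    bpp, bpd = bpm.bpp_bpd(pair_threshold)
    values = np.column_stack([phast, phast[up], phast[down], phylop, bpp, bpd])
    nuc_codes = np.zeros(n, dtype=np.uint8)
    n_mask = np.zeros(n, dtype=bool)
    seen_n = False
    for t, ch in enumerate(sequence.upper()):
        if ch == "N":
            nuc_codes[t] = 0
            n_mask[t] = True
            seen_n = True
        elif ch in NUC_TO_CODE:
            nuc_codes[t] = NUC_TO_CODE[ch]
        else:
            raise ValueError(f"invalid nucleotide {ch!r} at position {t}")
    if seen_n:
        warnings.warn("N nucleotides encoded as symbol 'A' and flagged")
    return RawFeatureSequence(values, nuc_codes, n_mask, offset)


@dataclass
class QuantileCodec:
    """Percentile boundaries mapping continuous values to symbols A-E (+F).

    ``boundaries[d]`` holds the 20/40/60/80th nearest-rank percentiles of
    the finite training values for dimension ``d`` (0-based, d1..d6).
    """

    boundaries: np.ndarray = field(default_factory=lambda: np.zeros((6, 4)))

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.shape != (6, 4):
            raise ValueError("codec requires 4 boundaries for each of 6 dimensions")
        if np.any(np.diff(self.boundaries, axis=1) < 0):
            raise ValueError("percentile boundaries must be non-decreasing")

    def encode_dim(self, dim: int, values: np.ndarray) -> np.ndarray:
        """Symbol codes for one continuous dimension (0-based ``dim`` < 6)."""
        values = np.asarray(values, dtype=float)
        codes = np.searchsorted(self.boundaries[dim], values, side="left").astype(np.uint8)
        if dim == 5:
            codes = np.where(np.isneginf(values), np.uint8(5), codes)
        return codes

    def to_json(self) -> dict:
        return {"boundaries": self.boundaries.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "QuantileCodec":
        return cls(np.asarray(obj["boundaries"], dtype=float))

    def dumps(self) -> str:
        return json.dumps(self.to_json())

    @classmethod
    def loads(cls, s: str) -> "QuantileCodec":
        return cls.from_json(json.loads(s))


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    s = np.sort(np.asarray(values, dtype=float))
    k = int(np.ceil(pct / 100.0 * s.size))
    return float(s[max(k, 1) - 1])


def fit_quantile_codec(training_values) -> QuantileCodec:
    """Fit per-dimension percentile boundaries from training feature values.

    ``training_values`` is a sequence of 6 collections of raw values (one per
    continuous dimension); ``-inf`` entries in dimension 6 are excluded from
    the percentile computation.
    """
    if len(training_values) != 6:
        raise ValueError("expected training values for 6 continuous dimensions")
    boundaries = np.zeros((6, 4))
    for d in range(6):
        vals = np.asarray(training_values[d], dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size < 5:
            raise ValueError(f"dimension {d + 1}: need >= 5 finite training values")
        if np.ptp(vals) == 0:
            warnings.warn(f"dimension {d + 1}: all training values identical; "
                          "degenerate codec")
        boundaries[d] = [nearest_rank_percentile(vals, p) for p in (20, 40, 60, 80)]
    return QuantileCodec(boundaries)


def encode(raw: RawFeatureSequence, codec: QuantileCodec) -> SymbolSequence:
    """Discretize a raw feature sequence with a fitted codec."""
    n = len(raw)
    codes = np.zeros((n, 7), dtype=np.uint8)
    for d in range(6):
        codes[:, d] = codec.encode_dim(d, raw.values[:, d])
    codes[:, 6] = raw.nuc_codes
    return SymbolSequence(codes)


def tracks_from_pairwise_alignment(blocks, alignment_probabilities,
                                   length: int) -> ConservationTracks:
    """Derive substitute conservation tracks from a pairwise alignment.

    For genomes without precomputed conservation scores, a pairwise
    alignment to a single related genome yields two stand-in tracks: the
    per-column match indicator (1 where the aligned nucleotides agree,
    else 0) substitutes for the per-column score, and the supplied
    per-column alignment probability substitutes for the run-based score.
    Unaligned positions score 0 on both tracks.

    Parameters
    ----------
    blocks
        Iterable of pairwise alignment blocks (e.g. Biopython MAF records);
        the first sequence of each block is the target and must carry a
        ``start`` annotation in target coordinates.
    alignment_probabilities
        One array of per-column probabilities for each block.
    length
        Length of the target sequence.
    """
    match = np.zeros(length)
    prob = np.zeros(length)
    blocks = list(blocks)
    if len(blocks) != len(alignment_probabilities):
        raise ValueError("one probability array required per alignment block")
    for bi, (block, col_probs) in enumerate(zip(blocks, alignment_probabilities)):
        try:
            ref, other = block[0], block[1]
            pos = int(ref.annotations["start"])
            ref_seq = str(ref.seq).upper()
            other_seq = str(other.seq).upper()
        except (IndexError, KeyError, AttributeError, TypeError) as exc:
            raise ValueError(f"malformed alignment block {bi}: {exc}") from exc
        if len(ref_seq) != len(other_seq) or len(col_probs) != len(ref_seq):
            raise ValueError(f"malformed alignment block {bi}: column count mismatch")
        for col, (a, b) in enumerate(zip(ref_seq, other_seq)):
            if a == "-":
                continue
            if pos >= length:
                raise ValueError(f"alignment block {bi} extends past the target sequence")
            if b != "-":
                match[pos] = 1.0 if a == b else 0.0
                prob[pos] = float(col_probs[col])
            pos += 1
    return ConservationTracks(phastcons=prob, phylop=match)
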