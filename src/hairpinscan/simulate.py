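"""Synthetic hairpin-bearing genomes with conservation tracks and labels.

The generator emulates the statistical structure the scanner relies on:

* a hairpin unit is ``[flank 20 nt][5'-arm][loop 8-20 nt][3'-arm][flank 20 nt]``
  where the 3' arm is the (lightly mutated) reverse complement of the 5' arm;
* the mature strand starts with U with high probability;
* the run-based conservation track is high over the duplex and loop, ramps
  down across the flanks, and dips sharply ~13 nt upstream of the duplex
  5' start and ~11 nt downstream of the duplex 3' end (the Drosha
  recognition base pair leaves exactly this signature);
* the per-column conservation track adds independent noise and elevates
  the mature arm over the passenger arm;
* background is random sequence with low conservation, salted with
  conserved decoy blocks (high conservation, no hairpin) so that
  conservation alone cannot separate positives from negatives.

Everything is driven by a single integer seed and is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import ConservationTracks

NUCS = np.array(list("ACGU"))
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_OK = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class HairpinSpec:
    """Shape parameters of a synthetic hairpin and its conservation profile."""

    mature_length_weights: tuple[tuple[int, float], ...] = ((22, 1.0),)
    arm_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)  # 5'arm, 3'arm, both
    loop_range: tuple[int, int] = (8, 20)
    stem_mutation_rate: float = 0.05
    duplex_conservation: float = 0.9
    flank_conservation: float = 0.2
    drb_dip_depth: float = 0.4
    drb_upstream: int = 13   # dip position upstream of the duplex 5' start
    drb_downstream: int = 11  # dip position downstream of the duplex 3' end
    noise_sd: float = 0.05
    phylop_noise_sd: float = 0.1
    mature_bonus: float = 0.15
    p_five_prime_u: float = 0.8
    flank_len: int = 20

    def __post_init__(self) -> None:
        if abs(sum(self.arm_probs) - 1.0) > 1e-9:
            raise ValueError("arm choice probabilities must sum to 1")
        if self.loop_range[0] < 3:
            raise ValueError("loop length below the steric minimum")
        if any(l <= 0 for l, _ in self.mature_length_weights):
            raise ValueError("mature lengths must be positive")


@dataclass
class HairpinUnit:
    """One synthetic hairpin with local coordinates starting at 0."""

    sequence: str
    labels: str
    pair_map: dict[int, int]
    phastcons: np.ndarray
    phylop: np.ndarray
    arm_mode: str               # "5p", "3p", or "both"
    duplex5: tuple[int, int]    # half-open intervals
    duplex3: tuple[int, int]
    loop: tuple[int, int]
    mature: list[tuple[int, int]]
    passenger: tuple[int, int] | None
    five_ends: list[int]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HairpinRecord:
    """A hairpin unit placed on a genome (absolute coordinates)."""

    start: int
    end: int
    unit: HairpinUnit

    @property
    def duplex_span(self) -> tuple[int, int]:
        return self.start + self.unit.duplex5[0], self.start + self.unit.duplex3[1]

    @property
    def five_ends(self) -> list[int]:
        return [self.start + p for p in self.unit.five_ends]

    @property
    def mature_intervals(self) -> list[tuple[int, int]]:
        return [(self.start + a, self.start + b) for a, b in self.unit.mature]


@dataclass
class SyntheticBundle:
    """A synthetic genome: sequence, tracks, truth records, and labels."""

    sequence: str
    tracks: ConservationTracks
    truth: list[HairpinRecord]
    labels: str
    decoys: list[tuple[int, int]] = field(default_factory=list)
    rng_seed: int = 0


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(NUCS, n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(NUCS[NUCS != out[i]]))
    return "".join(out)


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def generate_hairpin(spec: HairpinSpec | None = None,
                     seed: int | np.random.Generator = 0) -> HairpinUnit:
    """Sample one hairpin unit (sequence, pair map, labels, local tracks)."""
    spec = spec or HairpinSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths, weights = zip(*spec.mature_length_weights)
    lm = int(rng.choice(lengths, p=np.asarray(weights) / sum(weights)))
    mode = ["5p", "3p", "both"][int(rng.choice(3, p=spec.arm_probs))]
    loop_len = int(rng.integers(spec.loop_range[0], spec.loop_range[1] + 1))
    if loop_len < 3:
        raise ValueError("loop too short to close a hairpin")

    arm5 = list(_random_seq(rng, lm))
    if mode in ("5p", "both") and rng.random() < spec.p_five_prime_u:
        arm5[0] = "U"
    arm5 = "".join(arm5)
    arm3 = list(_mutate(rng, _revcomp(arm5), spec.stem_mutation_rate))
    if mode in ("3p", "both") and rng.random() < spec.p_five_prime_u:
        arm3[0] = "U"
    arm3 = "".join(arm3)
    loop = _random_seq(rng, loop_len)
    fl = spec.flank_len
    flank_l = _random_seq(rng, fl)
    flank_r = _random_seq(rng, fl)
    sequence = flank_l + arm5 + loop + arm3 + flank_r

    d5 = (fl, fl + lm)
    lp = (d5[1], d5[1] + loop_len)
    d3 = (lp[1], lp[1] + lm)
    pair_map = {}
    for k in range(lm):
        i = d5[0] + k
        j = d3[1] - 1 - k
        a, b = sequence[i], sequence[j]
        if _COMP[a] == b or (a, b) in _WOBBLE_OK:
            pair_map[i] = j
            pair_map[j] = i

    lab5 = "M" if mode in ("5p", "both") else "P"
    lab3 = "M" if mode in ("3p", "both") else "P"
    labels = "F" * fl + lab5 * lm + "L" * loop_len + lab3 * lm + "F" * fl

    n = len(sequence)
    phast = np.full(n, spec.duplex_conservation)
    ramp_up = np.linspace(spec.flank_conservation, spec.duplex_conservation, fl)
    phast[:fl] = ramp_up
    phast[n - fl:] = ramp_up[::-1]
    phast[lp[0]:lp[1]] = spec.duplex_conservation - 0.1
    for dip_center in (d5[0] - spec.drb_upstream, d3[1] - 1 + spec.drb_downstream):
        for off, frac in ((-1, 0.5), (0, 1.0), (1, 0.5)):
            p = dip_center + off
            if 0 <= p < n:
                phast[p] -= spec.drb_dip_depth * frac
    phast += rng.normal(0.0, spec.noise_sd, n)
    np.clip(phast, 0.0, 1.0, out=phast)

    phylop = phast + rng.normal(0.0, spec.phylop_noise_sd, n)
    mature_ivs = []
    if mode in ("5p", "both"):
        mature_ivs.append(d5)
    if mode in ("3p", "both"):
        mature_ivs.append(d3)
    passenger = None
    if mode == "5p":
        passenger = d3
    elif mode == "3p":
        passenger = d5
    for a, b in mature_ivs:
        phylop[a:b] += spec.mature_bonus
    if passenger is not None:
        phylop[passenger[0]:passenger[1]] -= spec.mature_bonus / 2.0

    five_ends = [a for a, _ in mature_ivs]
    return HairpinUnit(sequence, labels, pair_map, phast, phylop, mode,
                       d5, d3, lp, mature_ivs, passenger, five_ends)


def generate_genome(n_hairpins: int, background_length: int,
                    spec: HairpinSpec | None = None, seed: int = 0,
                    n_decoys: int | None = None, decoy_len: int = 200,
                    spacing: int = 200) -> SyntheticBundle:
    """A synthetic genome with planted hairpins and conserved decoy blocks."""
    spec = spec or HairpinSpec()
    rng = np.random.default_rng(seed)
    n_decoys = n_hairpins if n_decoys is None else n_decoys
    units = [generate_hairpin(spec, rng) for _ in range(n_hairpins)]
    lengths = [len(u) for u in units] + [decoy_len] * n_decoys
    needed = sum(lengths) + (len(lengths) + 1) * spacing
    if needed > background_length:
        raise ValueError(
            f"background of {background_length} nt cannot host "
            f"{n_hairpins} hairpins and {n_decoys} decoys with {spacing} nt spacing")

    seq = np.array(list(_random_seq(rng, background_length)))
    phast = np.clip(rng.normal(0.15, 0.1, background_length), 0.0, 1.0)
    phylop = phast + rng.normal(0.0, spec.phylop_noise_sd, background_length)
    labels = np.full(background_length, "N")

    placed: list[tuple[int, int]] = []

    def place(length: int) -> int:
        for _ in range(10000):
            start = int(rng.integers(0, background_length - length))
            if all(start >= e + spacing or start + length + spacing <= s
                   for s, e in placed):
                placed.append((start, start + length))
                return start
        raise ValueError("could not place all elements; genome overcrowded")

    truth = []
    for unit in units:
        start = place(len(unit))
        end = start + len(unit)
        seq[start:end] = list(unit.sequence)
        phast[start:end] = unit.phastcons
        phylop[start:end] = unit.phylop
        labels[start:end] = list(unit.labels)
        truth.append(HairpinRecord(start, end, unit))
    decoys = []
    for _ in range(n_decoys):
        start = place(decoy_len)
        end = start + decoy_len
        phast[start:end] = np.clip(rng.normal(0.75, 0.05, decoy_len), 0.0, 1.0)
        phylop[start:end] = phast[start:end] + rng.normal(
            0.0, spec.phylop_noise_sd, decoy_len)
        decoys.append((start, end))
    truth.sort(key=lambda r: r.start)
    decoys.sort()
    return SyntheticBundle("".join(seq), ConservationTracks(phast, phylop),
                           truth, "".join(labels), decoys, seed)


def deduce_passenger(mature: tuple[int, int], pair_map: dict[int, int],
                     repair_limit: int = 3) -> tuple[int, int]:
    """Passenger-strand interval implied by a mature interval and a pair map.

    Assumes the canonical duplex geometry in which both strands carry a
    2-nt 3' overhang.  For a mature strand on the 5' arm occupying the
    closed interval [a, b] with pairing partner function ``pi``, the
    passenger occupies [pi(b)+2, pi(a)+2]; the mirrored formula applies on
    the 3' arm.  Intervals are half-open; mature ends unpaired in the map
    are repaired to the nearest paired position (up to ``repair_limit`` nt).
    """
    a, b = mature
    if b - a < 2:
        raise ValueError("mature interval too short")
    a_c, b_c = a, b - 1  # closed interval ends

    def nearest_paired(pos: int) -> int:
        for k in range(repair_limit + 1):
            for q in (pos + k, pos - k):
                if q in pair_map:
                    return q
        raise ValueError(f"no paired position within {repair_limit} nt of "
                         f"position {pos}")

    probe = nearest_paired(a_c)
    if pair_map[probe] > b_c:  # partner downstream: mature on the 5' arm
        lo = pair_map[nearest_paired(b_c)] + 2
        hi = pair_map[nearest_paired(a_c)] + 2 + 1
    else:                      # mature on the 3' arm (mirrored formula)
        lo = pair_map[nearest_paired(b_c - 2)]
        hi = pair_map[nearest_paired(a_c - 2)] + 1
    if hi <= lo:
        raise ValueError("degenerate passenger interval")
    return lo, hi


def sample_background_regions(tracks: ConservationTracks, n_low: int, n_high: int,
                              window: int = 200, seed: int = 0,
                              exclude: list[tuple[int, int]] | None = None,
                              low_max: float = 0.4, high_min: float = 0.6,
                              max_attempts: int = 20000) -> list[tuple[int, int, str]]:
    """Non-overlapping 200-bp windows in conservation bands.

    Returns up to ``n_low`` windows with mean run-based conservation below
    ``low_max`` ("low") and ``n_high`` with mean above ``high_min``
    ("high"), avoiding the excluded intervals; a partial result triggers a
    warning.
    """
    rng = np.random.default_rng(seed)
    exclude = list(exclude or [])
    phast = tracks.phastcons
    n = tracks.length
    chosen: list[tuple[int, int, str]] = []
    counts = {"low": 0, "high": 0}
    want = {"low": n_low, "high": n_high}
    taken: list[tuple[int, int]] = list(exclude)
    for _ in range(max_attempts):
        if counts["low"] >= n_low and counts["high"] >= n_high:
            break
        start = int(rng.integers(0, n - window))
        end = start + window
        if any(start < e and end > s for s, e in taken):
            continue
        mean = float(np.nanmean(phast[start:end]))
        kind = "low" if mean < low_max else ("high" if mean > high_min else None)
        if kind is None or counts[kind] >= want[kind]:
            continue
        chosen.append((start, end, kind))
        taken.append((start, end))
        counts[kind] += 1
    if counts["low"] < n_low or counts["high"] < n_high:
        warnings.warn(
            f"only found {counts['low']}/{n_low} low and {counts['high']}/{n_high} "
            "high conservation windows")
    return chosen


def standardize_window(bundle: SyntheticBundle, record: HairpinRecord,
                       window: int = 200) -> tuple[int, int, str]:
    """A fixed-length labeled window centered on a hairpin's duplex.

    Returns (start, end, labels) on the bundle's coordinates; the hairpin
    is centered, the flank labels come from the planted unit, and the
    remainder is background.
    """
    d_lo, d_hi = record.duplex_span
    if record.end - record.start > window:
        raise ValueError("hairpin longer than the standardized window")
    center = (d_lo + d_hi) // 2
    start = int(np.clip(center - window // 2, 0, len(bundle.sequence) - window))
    end = start + window
    return start, end, bundle.labels[start:end]
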