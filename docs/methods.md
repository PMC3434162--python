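# Methods

## Scope and data flow

`hairpinscan` detects conserved miRNA precursor hairpins and the 5'-ends
of their mature strands from three inputs: genomic sequence (FASTA), a
run-based conservation track and a per-column conservation track
(bedGraph or fixed-step wiggle), and — for training — labeled intervals.
The pipeline is: fold → featurize → discretize → decode (or train).
All coordinates are 0-based half-open on the forward strand; the wiggle
reader is the single 1-based entry point.  Reverse-strand scanning
reverse-complements the sequence and reuses the (strand-symmetric)
conservation tracks.

## Folding and the structure features

Base-pair probabilities come from a McCaskill-style partition function
restricted to pairs with span ≤ `max_span` (default 120 nt, the window
length commonly used for genome-wide local folding).  Inside values are
computed in linear space per span band — safe because segment partition
functions under the span bound stay far below the float64 range (an
optional per-nucleotide rescaling covers spans beyond ~200 nt) — while
the exterior forward/backward passes run in log space.  Sequences longer
than ~10 kb are folded in overlapping chunks with a context margin of 25
spans per side; measured seam errors are below 1e-9.  An exhaustive
enumeration over all pseudoknot-free structures (≤ 20 nt) serves as the
test oracle for both the probabilities and the partition function.

### Energy model

Two pluggable scoring schemes are provided.  `simple` scores each pair in
isolation (GC 3, AU 2, GU 1 in units of `temperature_scale`).  This model
turned out to be qualitatively wrong for the package's purpose: with no
cooperativity between adjacent pairs, the conformational entropy of
scattered alternative pairings dominates, and even a perfect 6-bp GC stem
reaches at most ~0.74 pairing probability (a planted 22-bp duplex
~0.2) — verified against the enumeration oracle, so a property of the
model, not a bug.  The default `stacked` model therefore adds a stacking
score of 2 to any pair whose immediately nested neighbour also pairs,
the minimal analogue of the nearest-neighbour stacking terms in
thermodynamic parameter sets.  Under it, planted duplexes reach pairing
probabilities near 1 and the base-pair potential/distance features become
informative.  Both models run through the same inside–outside recursions
(the stacking branch adds one extra term each way) and both are checked
against enumeration to 1e-9.  A matrix from an external folding engine
can be substituted via `BasePairMatrix.from_pairs`.

### Feature vector

Per position: d1 = run-based conservation, d2/d3 = the same at ±20 nt
(clamped at sequence ends; the offset matches the flanking-chain length so
these dimensions see across the hairpin boundary), d4 = per-column
conservation, d5 = BPP (max pair probability), d6 = BPD (signed offset to
the most probable partner, −∞ when BPP < 0.5 — the probability level above
which the most probable pair is unambiguous; configurable), d7 =
nucleotide.  Missing track values are filled from the nearest covered
position; a wholly missing track becomes 0 with a warning.  N bases never
pair, are encoded as symbol A, and are flagged so downstream filters can
drop N-rich predictions.

### Discretization

Dimensions 1–6 are cut at the 20/40/60/80th percentiles of the finite
training values (nearest-rank convention; a value equal to a boundary
belongs to the lower symbol), giving symbols A–E; −∞ in d6 becomes F;
d7 maps A,U,G,C → A,B,C,D.  Fitting the codec on hairpin positions only
(the training windows) makes the symbol distribution informative exactly
where the sub-models need resolution.

## The CRF

215 emitting states in 12 sub-models: 1 background state (self loop),
2 flanking chains of 20 (no self loops — they fix the geometry around the
Drosha recognition base pair, ~13 nt upstream / ~11 nt downstream of the
duplex), 3 loop chains of 8 with per-state self loops, and 6 strand
chains of 25 with skip edges s → 25 for s = 17..24 so a traversal
consumes 18–25 positions.  Three duplex paths encode the mature strand on
the 5' arm, the 3' arm, or both.  No parameters are tied across
sub-models: the 5'-arm and 3'-arm Mature sub-models learn distinct
profiles, and left/right flanking are distinct.  Sequences are anchored
to start and end in the background state; because the background state
can be re-entered after a hairpin, one window may contain several
hairpins (this is the one deliberate cycle in the otherwise acyclic
graph).

Emission score of a symbol vector in a state is the sum of the seven
per-dimension weights (35 weights per state, 7 525 in total); every edge,
plus the start/end attachments, carries its own transition weight.

### Training

The objective per example is
`log Z_constrained − log Z`, the log-probability that a path drawn from
the CRF is consistent with the labels; both partition functions and their
expected-count gradients come from the same batched log-space
forward–backward engine, the constrained one by masking states whose
label differs from the annotation.  Infeasible labelings are reported
with the first position at which no labeled path can continue.  The
Gaussian prior is Σ mⱼ²/(2c) with a single constant c (larger c = weaker
shrinkage), its direction of use matching the selection grid
{0.1, 1, 10, 50, 100}.  Optimization is L-BFGS from the zero vector
(projected-gradient tolerance 1e-5, ≤ 500 iterations); everything
stochastic (splits, negative sampling) derives from one integer seed, so
refits are bit-identical.

Penalty selection splits the positive windows 80/20 (negatives sampled to
match the positive count in the training group), fits each grid value on
the first group, decodes the second, sweeps the probability threshold
grid (0.1..0.9), and keeps the c with the best F-score.

Training windows are 200 bp with the hairpin centered; flank labels F
cover exactly the 20 nt on each side of the duplex and everything else is
N, matching the flanking-chain span.  Negative windows are entirely N.
Real annotations with strand lengths outside 18–25 or flanks ≠ 20 are
reported by the label validator; the scanner warns and proceeds (the
constrained likelihood then treats the example through the nearest
feasible paths, which is a no-op when none exists — such examples raise).

### Decoding and calling

P^mi_i is the posterior mass off the background state; P^5end_i the mass
on the four Mature entry states (so P^5end ≤ P^mi everywhere).  Hairpin
segments are maximal runs with P^mi strictly above T kept at length
[80, 150); 5'-end calls are positions with P^5end > T, by default gated
to called segments (both thresholds default to the same T but are
independently settable, since evaluations sweep them separately).  Long
sequences are decoded in overlapping windows (default 2000/400) and each
position takes its posterior from the window whose center is nearest,
keeping it away from the background-anchored edges; interior stitching
error against a full-length decode is below 1e-6 on the synthetic
fixtures.

## Synthetic data

The generator emulates the statistical structure the scanner exploits,
not the biophysics.  A hairpin unit is
`[flank 20][arm 18-25][loop 8-20][complementary arm][flank 20]` with the
3' arm a lightly mutated (rate 0.05) reverse complement, mature length a
point mass at 22 nt, arm choice (0.45, 0.45, 0.10) for 5'/3'/both, and
the mature 5' nucleotide U with probability 0.8.  The run-based track
ramps from 0.2 (flanks) to 0.9 (duplex; loop 0.8) with a localized dip of
depth 0.4 at 13 nt upstream of the duplex 5' start and 11 nt downstream
of its 3' end; the per-column track adds independent noise (sd 0.1) and
elevates the mature arm by 0.15 (passenger lowered by half that).
Background is uniform random sequence with conservation ~0.15; conserved
decoy blocks (200 bp, mean ~0.75) make negatives that conservation alone
cannot reject.  Where the sources state no value, these defaults were
chosen once as field-plausible and are configuration, not assertions.

What the generator does *not* emulate: real dinucleotide composition,
repeats, overlapping genes, alignment artifacts, non-canonical hairpins
(mirtrons, multi-hairpin pri-miRNAs), or correlated noise between the two
conservation tracks beyond a shared mean.  Passing tests therefore show
that the machinery is correct and that the intended signals are
recoverable when present — not that real-genome accuracy matches the
synthetic numbers.  The generator's duplexes are blunt-ended for label
simplicity; the 2-nt 3'-overhang geometry is implemented in the
annotation utility `deduce_passenger` (passenger = [π(b)+2, π(a)+2] for a
5'-arm mature [a, b] closed, mirrored on the 3' arm; an involution on
perfect stems), which is how missing passenger annotations are deduced
for training.

## Evaluation

Sensitivity TP/(TP+FN), PPV TP/(TP+FP), F = harmonic mean; undefined
ratios (zero denominators) are reported as undefined, never silently 0.
Hairpin detection counts a truth hairpin as found when a called segment
overlaps it (≥ 1 nt by default; reciprocal overlap available).  5'-end
accuracy is evaluated within hairpin intervals only: calls match truth
sites within a tolerance of 0/1/2 nt, nearest pair first, each truth site
used once; calls outside hairpins are ignored (they have no defined
class).  The cross-validation harness holds out one fold (e.g.
chromosome), drops training examples sharing a family with the held-out
fold, selects c internally, and aggregates per-fold reports.

## Numerical and tie-break choices

- Percentiles: nearest-rank; boundary values belong to the lower symbol.
- BPD partner: strict maximum; ties keep the first candidate in scan
  order (downstream partners before upstream at equal distance).
- Segment runs use strict inequality (P^mi > T); length 150 is excluded.
- Log-space forward–backward throughout; posteriors sum to 1 within 1e-9.
- Empty sequences fold to empty matrices and decode to empty tracks.
- F-score ties during penalty selection resolve to the first grid value.

## Problem sizes

The shipped end-to-end experiment uses a 100-kb genome with 20 hairpins
and 20 decoys (the scale at which one run, including 5 penalty fits,
takes a few minutes on one CPU); unit tests use 8–20-kb genomes.  These
sizes were chosen so the whole suite exercises every stage at desk scale;
all scale linearly in genome length.

## Known limitations

- The energy model, even with stacking, is a caricature of a
  thermodynamic parameter set; absolute pair probabilities differ from
  Turner-model folders, so a codec fitted under one energy model must be
  used with matrices from the same model.
- Chunked folding and windowed decoding are local approximations with
  measured but nonzero seam effects.
- The label repairer is a validator-plus-warning, not a full projection;
  badly malformed annotations should be fixed upstream.
- Only canonical single-hairpin loci are modeled.
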