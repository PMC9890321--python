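# Methods

This note records the scientific model behind `vocalcomb`, the parameter
choices that matter, and what the synthetic tests do and do not establish.

## Hierarchy model

Vocalizations are modeled on three nested levels: **segments** (smallest
combinatorial unit, bounded by silences ≤ 0.025 s or sudden spectral
shifts), **calls** (1–7 segments), and **combinations** (2–5 calls separated
by silences ≤ ~0.5 s; silences > 1 s separate discrete vocal events).
Segment hand labels after relabeling are DS (down sweep), LH (long high),
NL (noisy line), SH (short high); the low-sample classes HL and US fold into
LH and SH respectively because their spectrogram clusters overlap.

Annotation conventions enforced by the reader:

- every segment must lie inside exactly one call, every call in at most one
  combination, every combination contains ≥ 2 calls (containment tolerance
  1 ms, absorbing annotation rounding);
- consecutive units on a tier overlapping by ≤ 1 ms are repaired by
  truncating the earlier unit at the later unit's start (boundaries placed
  where the intersection ceases); larger overlaps are format errors;
- the combination tier interval is treated as derived (first call start to
  last call end), not as an independent annotation.

The between-call merge threshold is 0.5 s with a +0.15 s tolerance by
default, reproducing the admission of gaps slightly above threshold (the
field rule tolerates deviations up to ~0.4 s; observed between-call maxima
sit near 0.6 s while discrete events are > 1 s apart).  Both numbers are
config parameters.

Between-call gap statistics pool only within-combination call gaps (the
alternative — pooling gaps around discrete calls — would mix two silence
populations; the discrete-call spacing is > 1 s by definition).

## Spectrogram standardization

Per unit: zero-phase Butterworth band-pass 0.4–8 kHz (order 5, applied
forward–backward), magnitude STFT (Hann window 512 samples, hop 128 at
44.1 kHz ≈ 11.6 ms / 2.9 ms), 64-band triangular mel filterbank over the
same band, amplitude compression log(1 + x/floor) with floor 1e-4, then
time standardization to 64 columns.

The STFT window/hop and the compression law are method choices the source
lineage leaves open; they are exposed in `PreprocessConfig` and recorded in
run manifests.

**Time log-rescaling.**  A unit of duration d occupies a support width of
`64 · ln(d/d₀) / ln(D/d₀)` columns (anchor d₀ = 1 ms, D = maximum unit
duration in the dataset), left-aligned and zero-padded on the right.  Two
deliberate choices:

- the anchor is the *dataset* maximum, so the longest unit always spans all
  64 columns and the map is self-contained and deterministic per dataset;
- the support width is **continuous**: the column straddling the support
  edge is scaled by its fractional coverage.  With a rounded (integer)
  width, two units differing by a fraction of a percent in duration can
  differ by an entire signal-vs-zero column, which dominates Euclidean
  distance and fabricates duration-quantization clusters in the embedding.
  The fractional edge column makes the representation Lipschitz in
  duration and removes that artifact (observed directly: the DS class of a
  synthetic corpus split into two spurious clusters by ±5% duration jitter
  under integer widths).

Units shorter than one analysis window (512 samples ≈ 11.6 ms) are logged
and skipped as degenerate.

## Projection and cluster evaluation

UMAP with n_neighbors 15, min_dist 0 (recommended for cluster evaluation),
Euclidean metric on the 4096 flattened bins, fixed `random_state` (forces
single-threaded, reproducible optimization).  Each predictor is evaluated
on one shared projection per dataset; the silhouette is computed on the 2-D
coordinates (config switch to score the 4096-D input instead).

The permuted-label test compares per-point silhouette coefficients under
the true labels against those under k randomly permuted labelings
(default k = 1, matching the reported two-group comparisons) with the
Kruskal–Wallis H statistic, df = k.  Caveat, verified empirically: because
both coefficient samples are computed on the same points, the groups are
dependent and the test is mildly anti-conservative under the null (~10%
rejections at nominal 5%).  The per-predictor *ranking* of S values, which
carries the scientific conclusions, is unaffected; p-values near the 0.05
boundary should not be over-read.  The balanced-subsample mode re-runs an
evaluation with every class downsampled to the smallest class count.

Every evaluation output carries per-individual row counts so
over-representation of a single caller is visible; the pipeline can cap any
individual's combination count (seeded random selection) before analysis.

## Transition analysis

Forward transition counts use adjacent ordered pairs **within** sequences
only — no cross-sequence pairs and no artificial start/end tokens.  Rows of
the probability matrix are normalized per source state; states with no
outgoing transitions keep all-zero rows.

The null randomizes the assignment of units to sequences by uniformly
permuting the flat token array over the fixed slot structure.  This
preserves exactly (i) each label's total frequency and (ii) the multiset of
sequence lengths.  Length preservation is an interpretation: it is required
for transition counts to be comparable between observed and null corpora,
and it matches the "assignment of units to sequences" framing.

Two-tailed significance per cell: p = min(1, 2·min(r₋, r₊)) where
r± = (#{null in tail} + 1)/(n_iter + 1), ties counting toward both tails
(conservative); the flag is set when the observed probability falls
strictly outside the central 95% of the null sample.  The p floor at
10 000 iterations is 1/10001 ≈ 1e-4.  A row state absent from the observed
corpus and every null draw is reported NA, not floor-significant.

Transitions are pooled across individuals (per-individual reruns are a
filtering step away); the call level uses the three broad call groups
(LH-containing / lone-NL / other) by default, with any call labeler (e.g.
the simplified repeated-segment-collapsed label) as an option.  Higher-order
and long-range structure is explicitly out of scope.

Verified properties: Monte-Carlo p-values converge to exhaustive-enumeration
p-values on tiny corpora; the flagged fraction on structureless corpora is
calibrated at ~5%; chains are recovered within 3 binomial SE at 10⁴
transitions; every observed and null matrix is row-stochastic to machine
precision.

## Synthetic corpus generator

The generator states a world, it is not fit to data:

- **Structure.**  Call-group sequences per combination come from a
  first-order chain over the three groups; segment sequences per call come
  from a first-order chain over {DS, LH, NL, SH}, rejection-sampled to match
  the call's group (an unconditioned mode samples calls straight from the
  segment chain — groups then emergent — so realized frequencies are
  unbiased chain estimates; used for parameter-recovery checks).  Default
  transition rows are the published estimates for this system (e.g. LH→DS
  = 1.0, NL→DS = 0.8, DS→SH = 0.75, SH→DS = 0.49).
- **Initial distributions and lengths.**  Both chains rarely transition
  *into* NL / lone-NL, yet those classes are well represented in the
  reference corpus — they must occur predominantly sequence-initially.
  Initial distributions (segments: DS .35, LH .05, NL .25, SH .35; groups:
  LH-containing .20, lone-NL .25, other .55) and decaying length weights
  (mean ≈ 2.5 segments/call, ≈ 2.6 calls/combination) are chosen so the
  realized composition resembles the reference corpus (1333 segments / 561
  calls / 222 combinations; class shares ≈ 35/15/13/32%).
- **Gaps.**  Fixed by default: 0.02 s between segments, 0.3 s between
  calls, 1.5 s between combinations — inside the stated regime and chosen
  constant so manifest gap statistics are exactly recoverable.
- **Acoustics.**  Invented (no per-class frequencies are published): DS a
  6.5→2 kHz sweep (0.15 s), LH a 2.8 kHz tone (0.30 s), SH a 5.2 kHz tone
  (0.07 s), NL 1–4 kHz band-limited noise (0.18 s); ±10% duration and ±3%
  frequency jitter; 5 ms cosine ramps.  All inside the 0.4–8 kHz analysis
  band and fully configurable.
- **Coarticulation injection** shifts acoustic parameters of segments in a
  chosen (class, position-category) cell — e.g. LH-preceding-DS +800 Hz, or
  combined-NL at 0.35× amplitude — creating the within-class two-cluster
  structure that position categories should then explain.

All times are quantized to the 44.1 kHz sample grid before rendering, so
TextGrid boundaries match the manifest within one sample; identical spec +
seed give byte-identical WAV and TextGrid files.

What green synthetic tests establish: the machinery (I/O, standardization,
projection, scoring, randomization) is correct and calibrated on a corpus
whose ground truth is known.  What they do not establish: robustness to
real-world nuisance — background noise, reverberation, amplitude variation
with distance, annotation error, within-class acoustic drift between
individuals — none of which the generator emulates.

## Degenerate inputs and tie-breaks

- Silhouette requires ≥ 2 classes with ≥ 2 members; degenerate predictors
  are reported with NaN scores rather than dropped silently.
- Kruskal–Wallis on identical-valued groups returns H = 0, p = 1.
- Observed-vs-null ties in the transition test count toward both tails.
- Empty corpora produce empty tables with warnings, not errors; a missing
  tier, orphan segment, or single-call "combination" is a hard error.

## Known limitations

- No automatic acoustic segmentation: annotations are given or synthetic.
- The permuted-label H-test calibration caveat above.
- Silhouette-on-projection inherits UMAP's layout stochasticity across
  seeds; seeds are therefore recorded in every output manifest.
- Short-format TextGrids and stereo audio are unsupported.
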