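# Methods

## The measurement model

A genomic tiling array measures transcription without gene models: 60-mer
probes start every 2 bp on both strands of the target sequence, so every
base is interrogated by 30 overlapping probes per strand.  Plant
mitochondrial genomes carry large (>10 kb) exact duplications; tiling both
copies would be redundant and ambiguous, so probe design first collapses
every exact repeat longer than 10 kb to its leftmost copy.  The circular
tiling convention — one probe start every `step` bp per strand with
wrap-around — makes the probe count equal the non-redundant length for
`step = 2` and two strands: an L-bp target carries L/2 starts per strand
and L probes in total.  (Linear per-segment tiling, `floor((L-60)/2)+1`
starts per strand per segment, is available; segments shorter than one
probe yield none.)

Repeats are found by seed-and-extend: 64-mer seeds are indexed, seed pairs
are extended to maximal exact matches in both orientations, and candidate
repeats are resolved greedily longest-first, keeping the leftmost copy.
Only exact repeats count — the duplications this stage exists for are exact
by construction, and near-identical repeat families are out of scope.
Repeats spanning the circular origin are not searched.

## Normalization

Sense and antisense probes at the same start are experimental replicates:
both strands carry the same double-stranded cDNA signal.  Each tissue's
channels (sense + antisense) are quantile-normalized together — every
column is replaced by the rank-wise mean of the sorted columns, with tied
values receiving the mean of the reference values their ranks span — and
then standardized to Z-scores with the sample (n−1) standard deviation.
Normalization is per tissue so that tissue-to-tissue distributional
differences are not erased; a cross-tissue mode exists behind a flag.
Whether standardization should happen before or after replicate merging is
not determined by the design; this implementation normalizes per channel
and then merges, which keeps each channel's distribution exactly standard.

## Expression calling

A sliding window of 60 consecutive probe positions (step 1, so ~120 bp of
starts; all replicate values pooled, n = 120 with both strands) is compared
against a background pool — every probe whose footprint lies fully within a
designated untranscribed control region — using the classic pooled-variance
two-sample Student's t-test, df = n_a + n_b − 2, two-tailed p.  With the
default two 620-bp control regions the pool holds 1124 replicate values
(2 regions x 2 strands x 281 fully contained probes).  A window is called
expressed when p < 0.001 **and** its mean exceeds the pool mean — a
one-sided gate on the two-tailed p, reconciling "exceeds the background"
with a two-tailed test.  No multiple-testing correction is applied: the raw
p < 0.001 rule *is* the calling criterion, deliberately, and its
consequences are measured rather than corrected (see Limitations).

Window p-values map back to probes by the `center` convention (a probe
takes the p of the window it centers; edge probes take the nearest full
window).  The `min_cover` alternative (minimum p over all covering windows)
is available for sensitivity analysis and smears calls by a full window.

Windows with zero pooled variance arise on noise-free synthetic data; they
take the limit convention (identical means → p = 1, different means →
p = 0), with tolerances (1e-10 on variance, 1e-8 on the mean difference)
far below the O(1) z-score working scale but above the round-off of the
running sums.

The transcribed fraction is the share of full-genome bases covered by at
least one significant probe footprint, with discarded duplicate copies
inheriting their kept representative's calls.

## Transcriptional units

A TU is a maximal run of at least 20 consecutive significant probes on the
merged, strandless track (probes every 2 bp, so >= ~98 bp of starts plus
the last footprint).  `gap_tolerance` (default 0, i.e. strictly continuous)
can bridge short non-significant gaps.  A TU overlapping a housekeeping
gene by >= 1 bp is gene-associated; the rest are inter-genic.  TU spans use
probe footprints (start of the first probe to end of the last), since a TU
is a genomic region, not a probe list.

Tissue comparison asks whether each TU of the sparser tissue is "also
identified" in the denser one.  The criterion is **query coverage**: a TU
counts as contained when a single TU of the other tissue covers >= 50% of
its span.  A reciprocal-overlap criterion is available (`mode="reciprocal"`)
but is not the default, because nested transcription — the seedling ⊂ calli
structure the data shows — routinely produces valid sub-TUs shorter than
half their parent, which reciprocal overlap would wrongly reject.

Per-region expression summaries average the z-scores of all probes fully
inside a region (regions without probes are recorded as missing, never
dropped); between-tissue agreement is the Pearson correlation of matched
region means, df = n − 2, p from t = r·sqrt(df/(1−r²)).

## ORFs and conservation

Six-frame ORF prediction defaults to stop-to-stop (maximal translations
between stop codons, the getorf-style default), with first-ATG-to-stop as
the alternative; the threshold is 70 aa, chosen because the shortest known
rice mitochondrial protein is 79 aa.  On circular genomes the scan runs
over the doubled sequence so ORFs may span the origin; each is reported
once, and a stop-free frame is capped at one full lap.  Translation is a
codon-table walk with the standard genetic code.  ORFs are numbered in
genomic (start, frame) order; frames overlapping a known gene on the same
strand by >= 1 bp keep their number but are not iORFs, so the iORF labels
skip those numbers.

Conservation screening reduces pairwise protein hit tables to reciprocal
best hits: (a, b) is an RBH iff b is a's best hit in one direction and a is
b's in the other, ties broken by subject id order.  Production input is
12-column tabular search output; for synthetic-species fixtures a built-in
local aligner (BLOSUM62, gap open −11 / extend −1) generates the tables.
Conservation-vs-expression association is a Pearson correlation between
each iORF's species count and its mean expression.

## The synthetic-data generator

The generator is the pipeline's ground truth.  It emulates:

- **Genome structure** — a circular molecule with non-overlapping
  housekeeping genes (1–3.5 kb), iORF regions (0.2–0.9 kb), TE fragments
  (0.3–1.5 kb), exact duplications of requested lengths (rightmost copy
  flagged, with mismatching flanks so the repeat length is exact), and
  untranscribed background-control regions of 620 bp each — sized so two
  controls carry exactly 1124 probe replicate values under the default
  tiling, matching the background-pool size the analysis assumes.
- **Transcription truth** — per-tissue interval sets hitting a requested
  genome fraction exactly (to the base pair), always covering every
  housekeeping gene, never touching a background control (200-bp buffer),
  and optionally nested (each sparser tissue's intervals inside the denser
  tissue's).  Free intervals are drawn around a typical length of 8–12 kb:
  at desk scale (100 kb standing in for ~490 kb) per-interval lengths are
  kept realistic at the expense of interval count, so that the caller's
  ~1-window boundary resolution stays small relative to covered length.
- **Intensities** — expected value = baseline + mean_signal x (fraction of
  the 60-bp footprint inside transcribed intervals), plus additive Gaussian
  noise; sense and antisense probes are independent draws around the same
  expectation.  Additive Gaussian on a log-like scale is the simplest model
  matching the t-test's assumptions; Z-scoring makes the absolute scale
  irrelevant.  Effect sizes are expressed in multiples of the noise sd
  (default effect 3, noise sd 1, baseline 10 — conventions, since no noise
  distribution is dictated by the measurement itself; they are explicit in
  the config).

One top-level seed is split deterministically per sub-generator
(`numpy.random.SeedSequence`), so identical calls are bit-for-bit
reproducible, including serialized outputs.

What the generator does **not** emulate: sequence-composition effects (GC
bias, cross-hybridization), probe thermodynamics, RNA editing, spatial
array artifacts, or heavy-tailed intensity noise.  Passing tests therefore
demonstrate the statistical machinery — calibration, power, run-length
logic, arithmetic — on data that satisfies the model's assumptions; they do
not certify behaviour under real hybridization artifacts.

## Calibration and recovery experiments

- **Null calibration**: 20,000 disjoint 60-probe windows on pure-background
  data, drawn in 50 independent batches each with its own 1124-value pool.
  Independent batches matter: windows sharing one pool are correlated
  through the pool mean, which would inflate the variance of the rejection
  rate beyond binomial.  The rejection count (two-tailed p < 0.001) is
  judged against the central 99% binomial interval.
- **Parameter recovery**: a 100-kb circular genome, two tissues with
  transcribed fractions 0.485 and 0.320 (nested), effect size 3, fixed
  seed.  The pipeline's recovered fractions land within ±0.02 of truth,
  every seedling TU is contained in a calli TU, and every housekeeping gene
  overlaps a called TU in both tissues.  The 100-kb size keeps the full run
  in a few seconds while preserving multi-kb interval lengths.

## Numerical choices

- Window statistics are computed from running sums centered on the pool
  mean, so identical window/pool data cancels exactly instead of losing
  precision over long cumulative sums.
- Quantile-normalization ties take the mean of the reference values they
  span (the dominant dialect; verified against limma's implementation on
  tie-free input).
- Pearson p-values use the exact t transform; |r| = 1 maps to p = 0.
- GFF3 output is 1-based closed; internal coordinates are 0-based
  half-open; origin-wrapping features are emitted as two part lines sharing
  an ID.

## Known limitations

- **Boundary smear**: window calling extends each true interval edge by
  roughly one window (~120 bp), so recovered transcribed fractions are
  biased upward by ~1–2 points on the 100-kb scenario (~18 edges).  This is
  a property of the sliding-window method itself, shared by any analysis
  using it, and is reported rather than corrected.
- **No multiple-testing control**: with ~50,000 overlapping windows per
  tissue, autocorrelated window p-values occasionally produce a spurious
  >= 20-probe run in a null region (a false TU); on rare seeds this breaks
  the otherwise-perfect nested containment.  The raw p < 0.001 rule is kept
  by design; users wanting control should lower alpha or raise `min_run`.
- Probes whose footprints cross non-redundant segment junctions map their
  whole footprint through the segment of their start; at 60 bp this is a
  sub-probe-length approximation at a handful of junctions.
- Repeat masking ignores repeats spanning the circular origin and
  overlapping (tandem) copies.
- Strand information is deliberately absent from calls: sense/antisense
  probes are replicates, so transcription calls are strandless.
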