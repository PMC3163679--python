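# Methods

## The model

After chemical transcription shutoff (e.g. cordycepin), transcript
abundance is assumed to follow first-order decay,

    N(t) = N(0) · exp(−k t),        ln(ratio remaining) = −k t,

with the half-life t½ = 0.693 / k.  The rounded constant 0.693 is used
by default for parity with the published microarray analysis; every
fitting entry point accepts `ln2_constant=math.log(2)` (`LN2_EXACT`)
for calibration work, where the ~2×10⁻⁴ relative difference would
otherwise dominate exactness checks.  Two-point series (0 vs 120 min)
use the closed form k = −ln(r₁/r₀)/Δt; longer series are fitted by
least squares on ln(ratio) versus time, with a free intercept by
default (robust to mis-scaled t = 0 values) and an optional
through-origin mode.  A fitted k ≤ 0 means no measurable decay: the
gene is *censored*, reported with t½ = +∞, never called unstable, and
excluded from correlation analyses.  Genes with t½ strictly below
60 min are called GUTs (genes with unstable transcripts).

## What the generator emulates

`synthetic_data` reproduces the statistical skeleton of a genome-wide
mRNA-stability experiment in an *Arabidopsis* allotetraploid:

- **Catalog** — 26,090 genes by default, of which a Bernoulli(0.008)
  subset (expected ≈ 209) is unstable.  Half-lives are uniform on
  (15, 59) min for unstable and (90, 600) min for stable genes; the
  uniform choice is a modeling convenience (no distributional claim is
  made by the source analysis) that keeps the classes separable at
  realistic noise.
- **Arrays** — one slide per (biological replicate, technical
  replicate, timepoint); the sample channel carries the allotetraploid
  RNA at time t, the reference channel the mid-parent pool.  Channel
  labels follow the dyes: even technical replicates are dye swaps
  (materials trade channels) and an additive `dye_bias_log2` (default
  0.10) always sits on the sample-dye channel, so the swap's sign flip
  cancels it.  Each channel gets i.i.d. log2 noise of SD
  `noise_sd_log2 / √2`, making the per-spot log2-*ratio* noise SD equal
  the configured `noise_sd_log2` (default 0.15, a typical two-color
  spot-level figure; the source experiment's own noise level is not
  published).
- **Coupling** — P(nonadditive | unstable) = P(nonadditive | stable) +
  `nonadditive_coupling` (clipped at 1; stable base rate 0.05, in line
  with genome-wide nonadditive-expression fractions reported for these
  hybrids), and the steady-state expression log2 ratio gets a negative
  linear loading on k so that expression and decay rate are negatively
  correlated whenever coupling > 0.
- **Categories** — 20 flat GO-slim-like labels with base membership
  probability 0.05; category 0's probability among unstable genes is
  boosted analytically so its expected fold enrichment in the unstable
  set equals `enrichment_factor` (default 3).
- **Promoters** — 1000-bp i.i.d. uniform ACGT sequences; a CBS
  (AAAAATCT) or extended evening element (AAAATATCT) is overwritten at
  a random forward-strand position with probability 0.5 for unstable
  and 0.1 for stable genes.
- **qPCR** — control-normalized relative abundance with expectation
  exp(−k_g t) per genotype and mean-one lognormal noise (ln-scale SD
  0.1); `parental_divergence` d scales parental decay constants to
  k(1 ∓ d).

What it does **not** emulate: scanner artifacts (spatial effects,
saturation, background), print-tip or intensity-dependent dye bias,
cross-hybridization between homoeologs, biological correlation between
genes, or qPCR amplification-efficiency effects.  Passing tests
therefore demonstrate correctness of the estimators under a clean
error model, not robustness to every artifact of real slides.

## Normalization and filtering

`normalize_arrays` floors non-positive intensities (ε = 1 raw unit,
genes with > 50 % floored spots dropped), computes per-slide log2
ratios, optionally median-centers each slide, and sign-flips dye-swap
slides.  Median-centering assumes the median gene is unchanged on a
slide; in a shutoff time course referenced against a t = 0-frozen pool
that assumption fails (the median gene itself decays), and centering
would subtract the bulk decay from every gene.  Synthetic slides are
generated on a common scale, so the pipeline default is the no-op mode;
"median" is intended for real slides with per-array channel imbalance,
where its bias toward the median gene's decay must be kept in mind.

Two hybridization-design readings are supported: each slide as
sample(t) vs common reference (temporal change = ratio(t) − ratio(0),
the default) or each slide directly comparing t vs 0.

Significance filtering mirrors the published criteria: a two-sided
one-sample t-test of replicate log2 ratios against 0 at α = 0.001 and
an inclusive two-fold rule (|mean log2 ratio| ≥ 1), required in every
dataset.  With only two technical replicates per biological sample a
per-sample t-test has one degree of freedom and can never reach
p ≤ 0.001, so the pipeline pools all replicate slides for the t-test
(df = 3 under the default 2×2 design) and applies the fold rule per
biological dataset.  Zero-variance degenerate inputs are reported as
p = 1 when the mean is 0 and p = 0 otherwise.

## Integration statistics

The GUT × nonadditive association is a Pearson chi-square on the 2×2
classification of the array universe, df = 1, without Yates correction
(immaterial at n ≈ 26,000; a flag enables it).  Expression–decay
correlation defaults to Spearman because the k distribution is
heavy-tailed; Pearson is available.  Clustering is agglomerative with
1 − Pearson distance and average linkage — the classic gene-expression
recipe — with zero-variance rows dropped and the ordered matrix
clipped to ±3 for display parity with log2 heat maps.

Fold enrichment is (n_set/set_size)/(n_genome/genome_size) per flat
category, multi-labeled genes counting once per category.  The
denominator convention is configurable: all supplied genes (default,
matching a proportion-of-the-whole-genome reading) or annotated genes
only.  The optional hypergeometric upper tail and Benjamini–Hochberg
adjustment are additions for reusable rigor; they default off to match
a ratio-only presentation.

Motif scanning is literal substring search; the evening element is
matched on its 7-mer core AATATCT with the AA prefix recorded as an
`extended` flag (strict mode requires it), reflecting the
parenthesized (AA) in the element's published notation.  Forward
strand only by default; reverse-complement scanning is a flag, with
'−'-strand coordinates mapped back to the forward sequence.

## Allo vs mid-parent contrast

The mid-parent value emulates a 1:1 physical RNA mix: the linear
(not log) mean of the parental series, pairing replicates when labels
match.  A 1:1 mix of two exponentials is not exponential; the fitted
k_mpv is its least-squares first-order approximation, and it is
bracketed by the parental constants for noiseless parents.  Whether
the allotetraploid decays faster than MPV is tested as a difference of
log-linear slopes via OLS on replicate-level ln(abundance) with a
genotype × time interaction (pooled residual variance,
df = n_allo + n_mpv − 4), two-sided, α = 0.05 by default — the
published analysis states significance without naming a test, so the
slope-difference t-test is this package's documented choice.  Under
the null with Gaussian ln-noise the test is exactly calibrated, which
the suite verifies empirically (rejection rate 0.05 ± 0.02 over 2000
simulations).

## Problem sizes and numerical choices

The recovery-style checks run one genome-scale replicate (26,090
genes, 2×2 replicates at 0/120 min, ratio-noise SD 0.15) — large
enough that binomial noise on the ~209-gene unstable class is a few
percent — plus an 8,000-gene full-pipeline run for the association
checks and 200–2000 Monte-Carlo replicates for power and type-I
checks.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations are
byte-reproducible.  Exactness assertions on the kinetics identity
(t½ × k = 0.693) use 10⁻¹² absolute tolerance; oracle-equivalence
checks use 10⁻⁹–10⁻¹⁰ relative tolerance.

## Known limitations

- The packaged 61-record reference table transcribes its source
  verbatim, including one locus (AT3G15210) printed twice with two
  half-lives; id-set operations on it therefore see 60 unique loci.
- Absolute half-life recovery from allo-vs-MPV co-hybridization is
  only identifiable when the reference pool does not itself decay;
  the generator models a t = 0-frozen reference.  With a decaying
  reference the arrays would measure *relative* (allo − reference)
  decay only.
- The ~1 % unstable yield under the published α = 0.001 / two-fold
  filters depends on the unpublished noise level of the original
  slides; the default `noise_sd_log2` is a placeholder calibrated only
  for class separability, not a claim about the original data.
- No multi-exponential or lagged decay models; genes with biphasic
  decay will be summarized by a single effective k.
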