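# Methods

## The problem

Two chromatin features can overlap on the genome for two different
reasons: because their signals rise and fall together (statistical
redundancy), or because they are wired together at a specific set of
loci despite being globally unrelated. The classic example is the
bivalent domain: H3K4me3 and H3K27me3 are essentially uncorrelated
genome-wide, yet in embryonic stem cells they co-occupy thousands of
promoters. This package scores feature pairs by how much their observed
colocalization exceeds what their statistical dependence predicts, and
carries the two downstream analyses that build on that idea: ranking
genes jointly broad in two markers, and splitting super-enhancers by
CTCF co-binding.

## The score

For each feature pair in a panel (several features across several cell
types) two quantities are measured:

- **I**, a mutual information between the two features' per-gene
  promoter signals (see below);
- **C_observed**, the genome-wide number of colocalization events,
  where an event is a (peak_a, peak_b) pair overlapping by at least
  1 bp. One A peak spanning two B peaks therefore yields two events;
  a merged-locus alternative (maximal regions covered by both tracks)
  is available behind `coloc_mode="merged"` for sensitivity checks.

A single ordinary least-squares regression of C on I, pooled over the
whole panel, gives each pair an expected count C_expected, and

    score = (C_observed − C_expected) / C_expected.

Large positive scores flag pairs colocalizing far beyond what their
dependence predicts. When the regression predicts C_expected ≤ 0 (it
can, at very low I) the score is reported as missing rather than
clamped — a clamped denominator would fabricate extreme values.

Each pair's residual is tested against zero with an externally
studentized residual (leave-one-out error estimate, leverage-corrected)
referred to a t distribution with n − 3 degrees of freedom, two-sided.
The choice of test is ours; its calibration is verified empirically in
the suite (p-values uniform under a simulated linear-plus-noise null,
Kolmogorov–Smirnov). The test needs at least 4 pairs; below that the
p-value is undefined. No multiple-testing correction is applied across
pairs.

## The information measure

The association measure is deliberately the per-gene-sum variant used
by the original analysis, not the textbook distribution-level MI
estimator. For gene i, let x_i be the summed signal of the feature's
peaks overlapping the promoter window (3 kb upstream to 10 kb
downstream of the TSS, strand-aware, clipped at position 0). Then

    H(X)   = Σ_i −P(x_i) log P(x_i)
    H(X,Y) = Σ_i −P(x_i, y_i) log P(x_i, y_i)
    I      = H(X) + H(Y) − H(X,Y)

with P(x_i) the Poisson probability of the (integer-rounded) observed
signal under a per-gene rate λ_i, computed in log space so that small
probabilities contribute exactly −p·log p → 0 rather than NaN.

Two modelling decisions were genuinely open and are exposed as modes:

- **Rate estimation (`lambda_mode`).** Default `promoter-mean`:
  λ_i = mean observed promoter signal across genes. The alternative
  `global` mode (λ_i = track-wide signal density × window width, a
  uniform-background expectation) is implemented but is *not* the
  default because it is numerically fragile: whenever the genome-wide
  signal density differs from the promoter-scale density by more than
  the Poisson tail width — which is the rule, not the exception, on
  any genome with concentrated signal — every pmf value underflows,
  all entropy terms vanish, and the measure becomes a constant. The
  promoter-mean rate is self-calibrating to the scale at which the
  entropy formula is informative. The mode used is recorded in every
  output.
- **Joint model (`joint_mode`).** Default `product-poisson`:
  P(x_i, y_i) = P(x_i)·P(y_i), the only reading consistent with the
  per-gene joint formula above. Note the consequence: under this model
  the per-gene sums make I ≈ H(X) + H(Y) up to small cross-terms, so I
  tracks the *individual surprise content* of the two tracks rather
  than their dependence. We keep it as the faithful default and provide
  `empirical-binned` as a standard cross-check: a plug-in histogram MI
  over B×B equal-occupancy bins (B = 16), for which I ≈ 0 on
  independent signals (up to the usual (B−1)²/(2n) bias, verified
  against a permutation null) and I = H(X) when Y = X. Note the
  binned mode sums over occupied bins, not over genes; summing the
  binned probabilities per gene would make I on independent data grow
  like n·log(B)/B, which defeats the purpose of a cross-check.

A useful property either way: entropies scale jointly under a change
of log base (natural log by default, `PairInformation.in_base`), and
the downstream score is invariant to that rescaling on exact-fit panels
because both observed and expected counts are unchanged.

One further sum-over-genes consequence, worth knowing when reading
outputs: H is extensive (duplicating every gene doubles it), so I
values are comparable only within a fixed gene universe.

## Gene ranking

Genes are ranked per marker by the total width of its promoter-window
peaks (rank 1 = broadest; ties break by gene id, zero-width genes sort
last, so ranks are always a permutation of 1..n). For a marker pair,
each gene gets the product of its two ranks, genes where the two
markers do not colocalize (≥ 1 bp peak-on-peak overlap inside the
promoter window) are removed, and the survivors sort by rank product
ascending. Gene groups take the top 500 by default. Set overlaps are
reported as counts plus percentages of a fixed denominator; marker
presence/absence across cell types ("lost in both", "retained in
both") is a ≥ 1 bp overlap test per region (promoter or gene body),
reported at both one-decimal and integer precision.

The rank-product formula is applied per gene (r1,i · r2,i); read as a
product over all genes it would collapse to a single scalar and could
not rank anything.

## Super-enhancers and CTCF

H3K27ac peaks within 12,500 bp are stitched into enhancers (no
TSS-exclusion window by default). Enhancers are ranked by total
constituent signal; with rank and signal both scaled to [0, 1], the
super/typical cutoff is the first point whose tangent slope reaches 1,
and enhancers strictly above it are super. The cutoff search is
vectorised but is checked against an exhaustive per-point slope scan.

High-confidence CTCF peaks are those with height strictly greater than
the upper quartile (linear-interpolation quantile) of the CTCF track's
peak heights. Super-enhancers containing ≥ 1 such peak are
CTCF-associated (CSE); the rest are OSE; the two classes partition the
supers exactly. CSE/OSE genes are genes whose body overlaps an
enhancer of the class by ≥ 1 bp; a gene touching both classes counts
as CSE (a deliberate precedence rule, logged). Where an ordered list
of class genes is needed, genes are ordered by the total signal of
their strongest overlapping enhancer of the class — the ordering
criterion is a package choice and marked as such.

The size-matched null: each typical enhancer is matched to a random
super-enhancer (with replacement, seeded) and grown symmetrically about
its midpoint to the matched width; clipping at position 0 pushes the
deficit to the other side so the final width always matches. Comparing
CTCF association rates of typical, enlarged and super collections asks
how much of the super-enhancers' CTCF association is explained by size
alone.

## Synthetic data

The generator plants the two axes the score separates — per-gene
signal correlation and genome-wide colocalization — independently:

- Genes sit on one chromosome, 30 kb apart, alternating strands, so
  promoter windows never collide. Each feature's promoter peak sits at
  a feature-specific offset inside the window, so promoter peaks of
  different features never overlap. Per-gene signals are multivariate
  normal (mean 100, SD 40·dispersion, clipped at 0) with the requested
  pairwise correlation matrix (PSD-checked up front; infeasible
  targets error before anything is written).
- Colocalization lives on a second chromosome laid out as 1-kb slots;
  widths and centre jitter are bounded so that peaks overlap iff they
  share a slot. Each feature's background slots come from a disjoint
  pool; a pair's planted slots are shared by exactly that pair. The
  pairwise event count therefore equals the planted target exactly.

The multi-cell-type study generator varies feature dispersions across
cell types. Under the per-gene-sum entropy, information *falls* as
dispersion rises (a dispersed observation is individually improbable
and improbable observations contribute ≈ 0 to −p log p), so background
colocalization targets are coupled to the numerically computed expected
entropy of each feature with additive Gaussian noise; the noise SD is
fixed analytically (σ = σ_signal·√(1/0.46² − 1)) so the background
rank correlation between information and colocalization sits near the
moderate positive coupling seen in real chromatin panels. Planted pairs
get high-dispersion (low-information) features and a colocalization
count far above background — the signature the score must rank first.

Enhancer fixtures are hockey-stick tracks (typical peaks: narrow,
unit-scale signal; supers: wide, `signal_ratio`-fold signal, positions
spaced beyond stitching range so the ground truth stays per-peak), with
CTCF planted inside enhancer peaks with probability increasing in the
width percentile plus uniform intergenic background along the same
chromosome.

What the fixtures do **not** emulate: read-level noise, peak-caller
artefacts, copy-number and mappability biases, overlapping/nested
peaks within one track, inter-chromosomal contact structure, and
realistic genome-scale peak counts. Passing tests show the algorithms
are implemented correctly and behave as designed in the regime they
target — not that any biological conclusion transfers to a particular
real dataset.

## Problem sizes and numerics

The suite and the reproduction script run the panel analysis at 15 cell
types × 6 features (225 pairs) with 150 genes and ~80 background peaks
per feature per cell type, 20 independently seeded replicates for the
planted-pair ranking, 100 random fixtures for the interval-count
oracle, and 1,000-enhancer tracks for the super-enhancer analyses —
sizes at which every planted effect is comfortably identifiable while
a full run stays in the minutes range on one core.

Numerical choices: Poisson pmf in log space; −p log p evaluated as
−exp(log p)·log p with the p = 0 limit mapped to 0; equal-occupancy bin
edges deduplicated under ties (heavily tied signals collapse bins
rather than erroring); OLS through a standard linear-model fit;
studentized residuals via the closed-form leave-one-out variance;
quantiles by linear interpolation. All randomness flows from explicit
integer seeds (study-level seeds are spawned from one root), and equal
inputs give byte-identical outputs.

## Known limitations

- The per-gene-sum information measure is nonstandard; under the
  product-Poisson joint it is close to H(X) + H(Y) and should be read
  as a surprise-content covariate, not a dependence estimate. The
  binned mode is the estimator to use when dependence per se matters.
- With few panel pairs (tens rather than hundreds) a single extreme
  pair has enough leverage to tilt the pooled regression and its own
  expectation; scores are most interpretable on panels of a couple of
  hundred pairs, as in the intended design.
- Plain BED input without a signal column supports width-based
  analyses only; information-theoretic scoring refuses such tracks
  rather than silently using widths as signals.
- Super-enhancer calling implements the scaled tangent-slope rule with
  stitching only; promoter-proximal exclusion and signal-vs-input
  subtraction, present in some pipelines, are out of scope.
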