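# Methods

## The assay and its statistical model

Pollen-typing measures recombination directly in gametes. Genomic DNA from
pollen of an F1 hybrid is diluted until PCR wells contain on average less
than one target molecule; allele-specific primer pairs amplify either
non-recombinant (parental) molecules or molecules recombinant in a marker
interval. Because the number of template molecules per well is Poisson, the
per-well probability of *no* amplification is the Poisson zero term:

- parental primers: `P(neg) = exp(−f·C·D)`
- recombinant primers: `P(neg) = exp(−f·r·C·D)`

with `C` the per-well concentration of the undiluted sample (molecules per
well), `D` the dilution (fraction of the undiluted sample per well,
dimensionless, 0 < D ≤ 1), `r` the recombination rate (proportion of
molecules recombinant in the interval), and `f` the amplifiable fraction per
primer pair. `f` defaults to 1/2: a parental primer pair amplifies one of
the two parental haplotypes, and a recombinant pair one of the two
reciprocal orientations. When both orientations are assayed, their series
are combined and `r` is the total two-orientation rate.

Each plate contributes a binomial likelihood for its negative-well count
`y` out of `N` wells. The joint posterior over `(C, r)` under independent
uniform priors is computed by a two-dimensional grid scan.

### Priors and grid

- `r ~ Uniform[0, r_max]`, `r_max = 0.1` by default (hotspot rates are
  percent-scale; 10% is a generous ceiling).
- `C ~ Uniform[C_lo, C_hi]`. Unless overridden, `C_lo = −ln(0.9)/(f·D_min)`
  (the least concentrated parental plate still expects ≥ 10% positive
  wells) and `C_hi = −ln(0.001)/(f·D_min)` (at most 99.9% positives there).
- Grid: 200 log-spaced `C` points × 200 linear `r` points by default
  (minimum 50 per axis). `C` spans orders of magnitude, hence the log
  spacing. Log-likelihoods are normalized by `logsumexp`; binomial terms
  use a log-space form stable when `P(neg)` underflows.
- Cell masses carry trapezoid quadrature weights, so a flat posterior
  integrates exactly: with parental data only, the `r` marginal reproduces
  its uniform prior cell by cell, and its 2.5/97.5% quantiles are exactly
  0.025·r_max and 0.975·r_max.
- Credible intervals are equal-tailed marginal quantiles obtained by
  linearly interpolating the piecewise-linear-density CDF between grid
  nodes. Mean and mode (highest marginal density) are both reported, since
  either could serve as the point estimate.
- If more than half the posterior mass lands in an outermost `C` cell, the
  scan aborts naming the offending prior bound: the data's likelihood peak
  lies outside the prior support, and a boundary-pinned "estimate" would be
  an artifact of the bound, not of the data.

### MPN quantification

`quantify_by_poisson` implements the classical most-probable-number
estimate `m = −ln(y/N)` molecules per well, with undiluted concentration
`m/(f·D)`. `y = 0` is rejected (m unbounded — dilute further); `y = N`
yields `m = 0` with a warning.

## Molecule classification

Calls over the ordered marker map are compared between consecutive
*informative* (non-missing) markers; each change of parental origin is a
transition, localized to the open interval between the two flanking
informative markers. Categories follow the transition count exactly:
0 parental, 1 CO, 2 NCO (the outer haplotype is necessarily restored),
\>2 chimeric. A molecule carrying a CO plus an independent conversion has
three transitions and is therefore labeled chimeric — the assay cannot
distinguish it from a discontinuous conversion. Indels are treated as point
markers at their left-most coordinate. Coordinates are 1-based inclusive;
BED exports convert to 0-based half-open.

## Hotspot shape

Breakpoint point positions are exchange-interval midpoints — the neutral
choice when the data are interval-censored at marker resolution. Interval
rates in cM/Mb apportion the locus genetic length (100·F cM, with F the
Bayesian or user-supplied CO frequency) by observed counts; the profile
integrates back to 100·F by construction.

The Gaussian fit minimizes the sum over inter-marker intervals of squared
differences between observed breakpoint fractions and the normal (or
K-component mixture) probability mass integrated over each interval. This
integrated-distribution criterion is insensitive to uneven marker spacing,
unlike fitting binned densities. The optimizer is multi-start Nelder–Mead
(12 starts), seeded from moment estimates (mixtures: cumulative-fraction
quantile spreads) with jittered restarts; σ is parameterized on the log
scale and mixture weights by softmax, making the search unconstrained.
`width95 = 3.92·σ` is the span of the central 95% normal mass. Fitting a
double hotspot as one 2-mixture or as two separate 1-component fits after
splitting at the valley are both supported (choose via the breakpoint
subset and `K`).

Orientation asymmetry: the separation statistic is the difference of
orientation-wise mean midpoints (P1toP2 minus P2toP1); the left/right ×
orientation association is tested by a two-tailed Fisher exact test on
counts split at the median breakpoint position (ties count as left). A
center-allele proportion (fraction of CO molecules carrying the first
parent's allele at a given position) is provided as a descriptive
transmission-bias statistic.

## Conversion tracts

For each NCO, `min = span of converted markers` (1 bp for a single SNP) and
`max = distance between the nearest non-converted flanking markers`; the
true tract always lies within [min, max] since conversion is detected only
at assayed polymorphisms. Events whose converted markers touch the map
edge have no flank on that side and are excluded from means (flagged
unbounded). Summaries are arithmetic means; the "averaged mid" is
(mean min + mean max)/2, reported unrounded with a nearest-bp rounding
convention for display. Chimeric (discontinuous) patterns are summarized by
their outermost converted markers and flagged, not averaged.

## Statistical tests

- **Fisher exact (2×2)**: one-tailed (lower tail in the top-left cell) and
  two-tailed (sum of all fixed-margin tables with point probability ≤
  observed). Backed by `scipy.stats.fisher_exact`; the test suite verifies
  it against a full hypergeometric enumeration oracle.
- **Binomial CI by CDF inversion**: both bounds solve
  `F(k; n, p) = target` at the *observed* count k (targets 0.975/0.025 for
  a 95% interval), by Brent root-finding with residual < 1e-10. This
  differs from textbook Clopper–Pearson (which uses k−1 in the lower-tail
  condition) and is the package-wide convention. Edge cases: k = 0 →
  lower = 0; k = n → upper = 1 and the lower bound uses the standard
  `alpha^(1/n)` closed form, since `F(n;n,p) ≡ 1` makes the generic
  condition unsolvable.
- **Partition chi-square**: Pearson 1-df statistic without continuity
  correction (Yates optional), rejecting tables with zero expected counts.
- **Rate ratios** are reported raw and optionally rounded (0 decimals for
  fold changes, 1 for ratios near 1).

## The simulator

Defaults describe a strong *A. thaliana* hotspot assay: `C = 2000`
molecules/well, `r = 0.0055`, one Gaussian component with σ = 376 bp
centred on the marker span, orientation offset δ = 213 bp, initiation bias
β = 0.8 toward the second parent's chromatid, NCO initiation rate 0.005
per genome, geometric tract lengths with mean 150 bp (the order of observed
few-hundred-bp maximal tracts), and three dilutions × 96 wells per primer
kind placed near the 50%-negative regime where the Poisson assay is most
informative.

What it emulates: Poisson well occupancy; interval-censored breakpoint
observation; reciprocal-orientation mean offset (±δ/2 per orientation);
tract ascertainment — an initiated conversion is only detected if its tract
covers a designated assay SNP, so detected NCO frequency underestimates
initiation whenever tracts are short relative to marker spacing. Tract
placement over the initiation site is uniform by default (left-anchored
available as a sensitivity mode). Out-of-region breakpoints are resampled
(truncation), preserving the Gaussian shape inside the region.

What it does not emulate: PCR false positives/negatives and allele-specific
primer mispriming, amplification efficiency gradients, crossover
interference between molecules, CO-associated conversion tracts, and
chimeric (template-switch) conversion patterns. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
sampling model, not robustness to these artifacts.

All generators derive their streams from a single integer seed; identical
seeds give identical outputs.

## Validation problem sizes

The recovery experiments use 50 replicate plate simulations on a 120×120
posterior grid for interval coverage, 10⁴ breakpoints for Gaussian shape
recovery, 2×10³ for offset recovery, exhaustive Fisher-oracle comparison
for table totals ≤ 20 plus 300 random tables at total 50, and 4×10⁴
genomes per tract-length point for the ascertainment monotonicity check.
These sizes put Monte-Carlo error well below the tolerances tested while
keeping the full suite under a minute.

## Known limitations

- The Bayesian model assumes every amplifiable molecule amplifies; partial
  PCR efficiency is absorbed into `C` and cancels out of `r` only if it is
  identical for both primer kinds.
- The integrated-distribution fit reports a local optimum; multi-start
  makes failures unlikely but pathological profiles (many empty intervals,
  K too large) are rejected rather than fitted.
- Tract bounds assume faithful genotyping of every assayed marker; a
  miscalled marker inside a tract converts an NCO into a chimeric pattern.
- `interval_rates` requires every breakpoint midpoint to fall inside the
  marker span; breakpoints at the map edge must be filtered first.
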