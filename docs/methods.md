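# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data generator, and the numerical and design choices behind the
`rmc` toolkit.

## Neutral expectation model

The unit of expectation is one possible missense substitution (one
transcript/position/ref/alt row). Its raw per-generation mutation rate
`mu` comes from a table keyed by trinucleotide context, alternate allele
and methylation level (an ordinal 0–2 by convention; the level count is
configurable). Two corrections map `mu` to the per-site expectation
contribution `mu_adj` in a specific reference cohort:

* **Plateau calibration.** A linear least-squares fit of the proportion of
  possible synonymous variants of each context actually observed in the
  cohort against `mu`, fitted separately per chromosome class
  (autosomal/pseudoautosomal, X, Y) and CpG status. Predictions are
  proportions and are clamped to [0, 1], since a linear fit can exit the
  unit interval at extreme rates.
* **Coverage correction.** Sites with median depth below a threshold
  (default 40x) are scaled down. The default form is a single scaling
  factor — observed synonymous count divided by the plateau expectation
  mass — applied uniformly below the threshold; an alternative linear
  model on log10(depth), fitted over low-coverage strata, is provided
  because the published description of the depth adjustment names the
  inputs but not the functional form. Both forms are config-selectable and
  should be treated as interpretations. Sites at or above the threshold
  are never corrected; zero-coverage sites are excluded upstream.

Expected counts over any site set are sums of `mu_adj` (computed with
compensated summation, so partitions re-aggregate exactly).

## Observed-variant criteria and OE

A possible variant counts as observed iff allele count > 0, allele
frequency < 0.001, it passes variant QC, and median coverage > 0. The
depletion ratio OE = obs/exp uses a 1e-9 floor on the expectation and is
capped at 1: the method targets depletion, and capping also makes the
section OE the maximizer of the Poisson likelihood over [0, 1], which
guarantees a non-negative likelihood-ratio statistic.

Transcript-level outlier exclusion (zero expectation in any of pLoF /
missense / synonymous, or Poisson z-scores beyond a configurable |z| > 4
for too many observed variants in any class or too few observed
synonymous) reproduces the spirit of the upstream QC flags; the exact
numeric bounds used upstream are not published, so the bound is config.

## Breakpoint search

Likelihoods are computed in log space with factorial terms dropped (they
cancel in the ratio). A breakpoint at coding position k assigns sites with
cds_pos <= k to the left section (closed-left). Positions are coding-
position boundaries: all alternate alleles at one position pool into one
entry of the cumulative arrays, so section sums are O(1) and the
single-break scan is O(n), the exhaustive pair scan O(n^2) per section
(vectorized in row chunks; no pruning heuristics — the contract is
exhaustive enumeration).

Parameters:

* `min_expected` (default 16) — every section created by a split must
  carry at least this much expectation; this is what keeps regions from
  collapsing to a handful of base pairs.
* `alpha` (default 0.001) — significance level. The published method
  states the level but not the reference distribution; the default here is
  a chi-square with df equal to the number of additional OE parameters
  (1 for a single break, critical value 10.828; 2 for a simultaneous pair,
  13.816), both configurable.
* Tie-break — when several positions attain the exact maximum chi2 the
  leftmost (smallest cds_pos) is taken, making outputs deterministic.

The recursion applies the single-break scan first; only if it finds
nothing significant does the pair scan run (mirroring the published flow);
any subsection produced by either split is then treated as an independent
transcript, and both scans are re-attempted inside it, until no
significant break remains. Whether the pair search should be re-attempted
inside subsections that a pair split created is not fully explicit in the
published description; this implementation assumes yes, which can only
find additional structure.

## Synthetic data

The generator emulates the statistical structure the search assumes.
Each coding position carries `n_alts` possible missense substitutions
(default 2 — real coding sequence averages about two possible missense
substitutions per position), each with expectation `mu_adj` (default 0.4
per substitution, upper-typical for the proportion of possible variants
observed at current reference-cohort sizes). Each substitution is observed
independently with probability `true_OE x mu_adj`, so region totals are
Poisson-binomial — indistinguishable from the Poisson model at these
rates — while the scan sees realistic site-level granularity. Planted
boundaries and OEs are returned as a truth record.

What the generator does *not* emulate: allele-frequency spectra (observed
is a flag, frequencies are nominal), context-dependent rate variation
within a transcript (per-site `mu` can be supplied but defaults to a
constant), exon structure (single-exon genomic mapping), and correlated
QC failures. Passing tests therefore demonstrate the statistical
machinery — calibration, power, localization, invariants — not robustness
to real-data artifacts.

Labeled-variant simulation draws the six MPC features from
class-conditional Gaussians with configurable mean shifts; cohort
simulation draws per-individual, per-bin Poisson variant counts at control
base rates times case multipliers.

A note on localization accuracy: the boundary estimate is the argmax of a
likelihood surface whose error behaves like a random-walk excursion around
the true boundary. Its scale depends only on the per-position observation
rates on the two sides, not on transcript length, so detection power grows
with expectation but localization does not. At the default density
(0.8 expected per position on the neutral side of a 0.2-vs-1.0 contrast)
about nine in ten detected boundaries fall within five positions of
truth; materially tighter localization requires per-position rates near
saturation, which current reference cohorts do not provide.

## MPC

Substitution-class metrics use 10 local-OE bins, left-closed right-open
([0,0.1), ..., final bin open-ended at 0.9+). The "second derivative" of a
class's OE across bins is estimated by central second differences on the
unit-spaced bin index, with the nearest interior stencil reused at the two
ends; bins without expectation mass are NaN and leave variants that fall
in them unscored. A variant's class-derivative feature is the value at the
bin containing its local OE (region OE where the transcript has multiple
regions, transcript OE otherwise).

The logistic fit (pathogenic = 1) is unpenalized by default, with an L2
fallback (and a warning) if the solve fails to converge, e.g. under
perfect separation; whether the published model was regularized or
standardized is not stated. Training uses only variants with all six
features.

The rank transform `d_i = −log10(max(0.83, f_i)/M)` counts benign training
variants with fitted value *strictly less* than the variant's, so scores
are reproducible pure ranks and invariant to any strictly monotone
transform of the fitted values. For `d_i` to increase with
deleteriousness, as the published description requires, the ranking
direction must be benign-ward; the stored fitted values are therefore the
negated pathogenic linear predictor. The 0.83 floor keeps the score finite
when a variant outranks every benign variant. Models persist to JSON with
the full sorted benign fitted-value vector (exact-count storage, for
bit-reproducible ranks).

Train/test transcript splits are stratified on the joint quantile bins of
s_het and the number of possible missense sites; assignment is
order-canonicalized so the split depends only on the id set and the seed.

## ACMG/AMP calibration

The local posterior at a grid point is the pathogenic fraction among the
k nearest labeled variants by score (default k = 100), re-weighted on the
odds scale from the labeled sample's prevalence to a target prior (default
0.0441, the canonical value of the published point-based framework, whose
own calibration prior is not printed). Windows are fixed score intervals
determined by the original sample; the one-sided 95% bounds come from a
seeded nonparametric bootstrap over variants, and a grid point whose
window holds fewer than a configurable minimum of variants is undefined,
never extrapolated. The curve stores both the lower and the upper bound
because the pathogenic direction thresholds on the stringent-low side and
the benign direction on the stringent-high side of the same curve.

Evidence odds are c = 350 for very strong and c^(1/2), c^(1/4), c^(1/8)
for strong/moderate/supporting (reciprocals for benign), converted to
posterior cutoffs through the prior. The score cutoff for a strength is
the most permissive grid score whose confidence bound meets the cutoff in
an unbroken run from the relevant extreme of the grid; requiring the run
to be contiguous makes cutoffs monotone across strengths by construction,
and thresholding on the bound rather than the point estimate can only be
more conservative.

## Enrichment statistics

Rate ratios divide per-individual variant rates; the p-value and CI come
from a binomial test of the case/control split of variant counts against
the cohort-size proportion, with the proportion CI transformed to the
ratio scale (the per-variant-count construction; whether the published
figure CIs were computed per variant or per individual is not printed).
Zero control counts give an infinite estimate with a one-sided interval.
Top-percentile odds ratios pool case and control scores, take the top
percentile with boundary ties included (the inclusive convention is a
choice; the alternative excludes ties), and report the Fisher exact p with
a Woolf logit CI (Haldane correction at zero cells). OE bins are
left-closed right-open with an open-ended final bin; empty bins are
undefined rather than zero.

## Problem sizes

The test suite and the acceptance script size their simulations to what
the properties need rather than to the published genome-wide scale: 200
seeded transcripts for recovery and 500 for null calibration (transcripts
of 150–300 positions, 48–120 expected events), 15–50 instances for
brute-force oracle equivalence (pair enumeration is quadratic), 1000
bootstrap draws for calibration, and exact Fisher enumeration over all
2x2 tables with grand total at most 30. These sizes give the fractions
reported by `scripts/acceptance.py` sampling errors of a few percent.

## Known limitations

* Linear sequence only: depletion clustered in 3D structure but spread in
  sequence is invisible, and non-canonical transcripts are out of scope.
* Missense enrichment (OE > 1) is deliberately not detected (capping).
* The low-coverage correction's published functional form is unknown;
  both provided forms are labeled interpretations.
* Single-amino-acid resolution is beyond current reference cohort sizes;
  the minimum-expectation rule enforces this honestly.
* The generator's idealizations listed above mean real-data performance
  depends additionally on annotation and QC quality.
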