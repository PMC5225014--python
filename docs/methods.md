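# Methods

## Study design being modelled

Twenty piglets (5 litters × 4, sexes balanced within litter) are followed
from the first post-natal week through weaning into a deliberately
challenging environment. Fecal dry matter (DM) defines the outcome: a pig
is diarrhoeic (D) if DM drops below 20 % on at least two consecutive
observed days, healthy (H) otherwise. The scientific question is whether
microbiota measurements taken before weaning already separate the two
groups. All group labels used downstream come from this a-posteriori DM
classification (a flag switches to ground-truth labels for power studies).

## Fingerprint processing

Electrophoresis traces are aligned by monotone (PCHIP) interpolation
through the internal size-standard anchors, extended linearly beyond the
outermost anchors; the baseline is a rolling minimum over 5 % of the trace
length, smoothed by a moving average of the same width, subtracted and
floored at zero; the trace is scaled to unit trapezoidal area. Area rather
than height normalization was chosen where the convention was ambiguous;
with unit total area the two differ only by peak-shape effects.

Peaks are local maxima above `min_rel_height` (default 0.05) of the global
maximum; each peak's area integrates between the lowest points separating
it from its retained neighbours, and areas are renormalized to sum to one.

Diversity is reported as Gini–Simpson (`1 − Σp²`, so higher = more
diverse; the inverse-Simpson form is available), Shannon, richness (peak
count) and Pielou evenness `H / ln S` (set to 1 when S = 1). Fingerprint
software historically reports an "equitability" index whose formula varies
between packages; where a legacy analysis shows diversity and evenness
moving in opposite directions at the same time point, Pielou evenness on
identical peak areas will not necessarily reproduce it. Both indices are
emitted; the discrepancy is documented rather than resolved.

Binary profiles are built by single-pass position binning (ascending
order; a peak joins the current bin while within 0.5 size units of the
bin's first member, ties to the earlier bin) and compared with Jaccard
distance. ANOSIM uses Clarke's statistic — midranks of all n(n−1)/2
distances, `R = (r̄_B − r̄_W) / (n(n−1)/4)` — with
`p = (1 + #{R_perm ≥ R_obs}) / (1 + N)` over N sampled label permutations
(default 999) so p can never be zero; an exact mode enumerates all distinct
assignments for small n. Hierarchical clustering defaults to UPGMA (the
linkage is configurable; nothing in the analysis depends on it) and exports
Newick.

## Differential abundance

OTUs are kept when their total count exceeds 3 (strict) and the variance of
their per-sample relative abundances exceeds 1e-8; the variance filter's
domain (raw vs relative counts) is configurable, relative abundances being
the default because the filter's purpose is to drop features constant in
composition. Scaling factors are median-of-ratios against the geometric
mean reference over OTUs present in all samples, rescaled to geometric mean
one, with a total-count fallback (logged) for tables with no common OTU.

A single common NB dispersion φ (variance `μ + φμ²`) is estimated by
conditional maximum likelihood: counts are first adjusted to a common
library by dividing by the scaling factor and rounding half-up (the crude
limit of quantile matching — full NB quantile matching needs φ itself and
was judged unnecessary at this scale, see the parameter-recovery tests);
given the per-group sums the counts are Dirichlet-multinomial with
concentration 1/φ, free of the per-OTU means, and the summed log-likelihood
is maximized on a log grid. φ = 0 (Poisson) is handled as the boundary.

The exact test conditions on each OTU's two-group sum s: under equal
means the group-1 sum is distributed over a = 0..s proportionally to
`NB(a; n₁/φ, p)·NB(s−a; n₂/φ, p)` (binomial in the Poisson limit), and the
two-sided p sums every split no more probable than the observed one
(doubling the smaller tail is available). log₂ fold changes use group means
of normalized counts with a 0.125 prior per group so structural zeros stay
finite — large |log2FC| for all-zero-in-one-group OTUs, never ±∞. FDR is
Benjamini–Hochberg step-up.

## Sparse PLS-DA and stability selection

X is centered and unit-variance scaled; Y is the centered/scaled two-class
indicator matrix. Per component the dominant singular pair of `X'Y` is
computed by alternating power iterations with soft-thresholding: the keepX
largest |weights| survive and shrink by the largest excluded magnitude (the
standard ℓ1 surrogate in sparse PLS); boundary ties resolve by feature
order, a survivor tied exactly at the threshold retaining an infinitesimal
weight so the nonzero count is exactly keepX and runs are reproducible.
X is deflated by regression on the score, making score columns orthogonal.
Prediction projects new samples through the rotation `W(P'W)⁻¹` and assigns
the nearest class centroid in score space (Euclidean; exact ties go to the
first class in sorted label order; a maximum-distance rule is not needed
for two balanced centroids and was left out).

Stage 1 grid-searches ncomp ∈ {1,2,3} × shared keepX ∈ {5,…,50} by
stratified 5-fold cross-validation repeated 10 times (stratification is
essential at n = 20 with a 13/7 imbalance; one fit per (keepX, fold) is
evaluated at every ncomp since components are nested). Ties prefer fewer
components, then fewer features. For the winning configuration each
feature's selection frequency across all folds × repeats is recorded;
the stable set is the features at frequency exactly 1 on some component,
falling back (logged) to a configurable frequency threshold when empty.
Stage 2 re-tunes keepX on the stable set only (the restricted keepX is not
meaningful to carry over) and reports the second cross-validated error.
The expected ordering — stage 2 no worse than stage 1 on signal-bearing
data, both at chance on noise — is what the tests pin down; absolute error
rates are data-dependent. Note that the *minimum* CV error over a tuning
grid is optimistically biased, so chance-level behaviour on pure noise is
asserted at a fixed configuration, not at the grid minimum.

## sPLS, networks, associations

General sparse PLS supports regression mode (Y deflated by X scores) and
canonical mode (each block by its own scores); regression mode can use up
to rank(X) components, canonical mode is capped at min(p, q). The
relevance-network similarity is the bilinear reconstruction
`Σ_h cor(xⱼ, s_h)·cor(y_k, s'_h)`; in regression mode both blocks project
on the X scores, which makes the keep-all similarity equal the Pearson
cross-correlation matrix exactly once ncomp reaches rank(X) (this is the
tested invariant), while canonical mode uses each block's own scores.
Edges are kept at |similarity| > 0.5 with their sign. The OTU–pathway
association matrix is the same similarity from a canonical-mode fit
(pairwise Pearson available by flag), with rows and columns ordered by
average-linkage clustering for heatmap rendering.

A caution for users: the first sparse-PLS score pair *maximizes*
cross-block covariance, so even independent blocks show strongly positive
score correlations at small n. Null behaviour should be judged on the
similarity entries (which do concentrate near zero) or against a
permutation baseline, never on the raw score correlation.

## qPCR and cohort statistics

Standard curves are least squares of Cq on log₁₀ copies over a 10-fold
dilution series; efficiency is `10^(−1/slope) − 1`; unknowns are
`10^((Cq − intercept)/slope)` rescaled to copies per 100 µg DNA, flagged
(not rejected) when Cq falls more than 3 cycles outside the standards'
range. Group comparisons gate on Shapiro–Wilk per group at α = 0.05 —
both normal → Student's t, otherwise Mann–Whitney; groups under 3 samples
force the nonparametric branch. Age effects within group are paired t-tests
between consecutive ages (the literal reading of a repeated-measures
description that conflates two procedures; a mixed model is out of scope).
Enterobacteriaceae–DM correlations are Pearson within the liquid (< 20 %
DM) and solid subgroups separately. MUC13 alleles are called at 151 bp (A)
and 83 bp (B) within ±2 bp; allele counts per group form a 2×2 table tested
by Pearson χ² without continuity correction (Yates by flag). Colostral
loads multiply concentration by intake with explicit mass/volume unit
checking.

## Synthetic cohort generator

The generator emits the full stated world with known ground truth; all
randomness derives from one root seed through named independent streams
(cohort, counts, traces, qpcr, phenotypes, pathways), so stages regenerate
independently and byte-identically.

- **Cohort**: 5 litters × 4 pigs, 2M/2F per litter; per-litter D counts
  default (3,3,3,2,2) = 13 D / 7 H (the commonly quoted per-litter pattern
  of 3,3,3,1,1 sums to 11 and is internally inconsistent with a 13/7
  split; the prevalence is a parameter, not a constant).
- **Counts**: per-cell NB with variance `μ + φμ²`, shared φ = 0.2,
  log-normal baseline composition, libraries uniform on 8 000–12 000
  (a desk-scale stand-in for amplicon depth), group effect multiplicative
  and symmetric (±log2FC/2), so label swap negates log2FC exactly.
  Defaults plant 15 discriminant OTUs at |log2FC| = 3. Taxonomy cycles
  through common pig-gut families (Prevotellaceae, Lachnospiraceae,
  Ruminococcaceae, Lactobacillaceae, Fusobacteriaceae, Corynebacteriaceae,
  Enterobacteriaceae, …).
- **Fingerprints**: injective OTU→position map (optional forced
  co-migration for stress tests), Gaussian peaks of fixed width 1.2 size
  units with area ∝ relative abundance, a smooth low arch baseline,
  optional white noise and a per-sample uniform scan shift; size-standard
  peaks at 50–450 are reported at their shifted positions.
- **qPCR**: standards at 10-fold dilutions 10³–10¹⁰ with
  `Cq = intercept − log₁₀(copies)/log₁₀(1 + efficiency)` (efficiency
  default 0.95, intercept 38); unknowns derive from true copies per 100 µg
  scaled by a random DNA input mass.
- **Phenotypes**: daily DM from day 30 to 47. D pigs get one episode of
  2–3 consecutive days starting uniformly on days 38–42; episode DM is
  `19.5 + slope × excess` where excess is the pig's day-38 log₁₀
  Enterobacteriaceae elevation (slope default −3 DM% per log₁₀), H pigs
  stay above 20 % throughout. Enterobacteriaceae is elevated in D pigs
  from day 30 on (half effect before day 38), emulating a load that
  precedes clinical signs. MUC13 alleles (A at 60 %) are drawn
  independently of group; colostrum intake ~N(300, 50) mL and
  immunoglobulin concentrations at physiologically plausible means.
- **Pathways**: a sparse nonnegative mixture of OTU relative abundances
  plus noise — structure enough for association tests, with no claim to
  emulate real functional imputation.

What a green test does *not* establish: the generator draws each OTU
independently (no compositional or ecological covariance), places peaks
injectively by default (real fingerprints co-migrate), uses one sample per
pig per stage (no repeated-measures correlation), and couples DM to a
single taxon through a clean linear rule. Effect recovery on this world
bounds implementation correctness, not real-data performance.

## Numerical choices and degenerate inputs

- Exact-test p-values compare probabilities with a relative 1e-12 guard so
  float noise cannot drop the observed outcome from its own tail.
- The dispersion optimizer works on log φ over [1e-10, 50] and reports 0 at
  the lower boundary.
- Soft-threshold tie-breaks and the sign convention (largest |weight|
  positive) make every fit deterministic.
- All-zero traces, < 2 standard peaks, empty peak-set pairs, one-class
  fits, single-sample groups and negative concentrations raise immediately
  with named errors rather than propagating NaNs.
- Cross-validation folds shrink (with a warning) when the smallest class
  cannot fill them.

## Known limitations

Two-class discrimination only; a single common dispersion (no tagwise
shrinkage or GLMs); no compositional (log-ratio) methods; no mixed-effects
modelling of litter; no chromatogram file-format parsing; no read-level
simulation. Printed figures from any particular real cohort (error rates,
stable-OTU counts, specific R or r² values) are data-dependent and are used
here only as ordering properties on synthetic data.
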