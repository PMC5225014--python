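# weanling

Statistical pipeline for asking whether the **early-life fecal microbiota of
piglets predicts later susceptibility to post-weaning diarrhoea**. A cohort
of suckling piglets (5 litters × 4 pigs) is weaned into a challenging
environment and *a posteriori* split into diarrhoeic (**D**, fecal dry
matter < 20 % on ≥ 2 consecutive days) and healthy (**H**) animals; the
pipeline then tests whether microbiota measurements taken weeks earlier
already separate the two groups.

It is aimed at microbial-ecology researchers who want the full analysis —
from raw fingerprints and count tables to discriminant OTU lists and
relevance networks — as reusable, tested Python, together with a synthetic
cohort generator so every stage can be validated against known ground truth.

## What it computes

- **Fingerprint diversity** (CE-SSCP-style traces): size-standard
  alignment, baseline subtraction, area normalization, peak calling; with
  peak areas *pᵢ*: Gini–Simpson `1 − Σpᵢ²`, Shannon `−Σpᵢ ln pᵢ`, richness
  *S*, Pielou evenness `H / ln S`.
- **Community comparison**: binary (presence/absence) phylotype profiles,
  Jaccard distance `1 − |A∩B| / |A∪B|`, **ANOSIM** with Clarke's
  `R = (r̄_between − r̄_within) / (n(n−1)/4)` at 999 permutations, and UPGMA
  clustering.
- **Differential OTU abundance**: total-count and variance filtering,
  median-of-ratios scaling factors, a common negative-binomial dispersion φ
  (variance `μ + φμ²`) by conditional maximum likelihood, a **two-sided
  exact NB test** conditioning on each OTU's two-group sum, and
  Benjamini–Hochberg FDR.
- **Two-stage sparse PLS-DA**: per component the dominant singular pair of
  `X'Y` soft-thresholded to exactly `keepX` nonzero loadings; stage 1 tunes
  `(ncomp, keepX)` by stratified repeated cross-validation and records each
  OTU's selection frequency over all folds × repeats; stage 2 refits on the
  OTUs selected in *every* fold (stability = 1).
- **sPLS relevance networks**: regression/canonical sparse PLS between OTUs
  and qPCR abundances or pathway matrices; edges where the bilinear
  similarity `Σ_h cor(xⱼ, ξ_h)·cor(y_k, ξ_h)` exceeds |0.5|.
- **Cohort statistics**: qPCR standard curves (`Cq = a + b·log₁₀ copies`,
  efficiency `10^(−1/b) − 1`) and absolute copies per 100 µg DNA; the
  dry-matter diarrhoea rule; Shapiro-gated t / Mann–Whitney comparisons;
  Enterobacteriaceae–dry-matter correlations split at 20 % DM; MUC13
  genotyping (151 bp = A, 83 bp = B) with Pearson χ²; colostral
  immunoglobulin intake arithmetic.

## Worked example

```bash
weanling run-all --seed 11 --outdir demo --repeats 5
```

```
simulate: {'pigs': 20, 'otus': 150, 'samples': 20}
cohort-labels: {'pigs': 20, 'n_D': 13, 'agrees_with_truth': 20}
fingerprint: {'samples': 20, 'anosim_R': 0.5907425907425907, 'anosim_p': 0.001}
diffabund: {'otus_in': 150, 'otus_after_filter': 149, 'dispersion': 0.20079450187636735, 'significant_fdr': 15}
splsda: {'stable_otus': 2, 'first_stage_error': 0.0, 'second_stage_error': 0.0}
network: {'edges': 5, 'pathway_matrix': [2, 40]}
cohort-stats: {'muc13_chi2': 3.2367632367632364, 'muc13_p': 0.07200275699657543, ...}
```

Reading this: the generator planted 13 diarrhoeic pigs and the dry-matter
rule recovered all 20 labels; the binarized fingerprints separate the
groups well (ANOSIM R = 0.59, p = 0.001 — 0 would be random grouping, 1
perfect separation); the exact NB test flags 15 OTUs at FDR < 0.05 with a
dispersion estimate of 0.20 (the generator's true φ = 0.2); the two-stage
sPLS-DA classifies the groups with zero cross-validated error. In
`demo/entero_dm_correlation.tsv` the liquid-feces subgroup shows
r² = 0.998 between log₁₀ Enterobacteriaceae copies and dry matter while the
solid subgroup shows r² = 0.014 — the planted coupling of bacterial load to
diarrhoea severity in D pigs only.

Each stage is also available on its own (`weanling simulate / fingerprint /
diffabund / splsda / cohort`) and as plain library calls (`weanling.diffabund.
exact_test`, `weanling.splsda.tune_and_stability`, ...), all consuming and
producing TSV.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch via the package's ANOSIM implementation, (t1) the
mean R statistic over 200 datasets of 20 samples with i.i.d. uniform
dissimilarities and randomly assigned 10/10 labels, and (t2) the R
statistic of a constructed 4+4 dataset in which every between-group
dissimilarity exceeds every within-group one, writing both to the JSON file
given by `--out`.

See `docs/methods.md` for the statistical model, the synthetic-data
generator's assumptions, and numerical choices.
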