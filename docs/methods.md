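# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limits of what the test suite demonstrates.

## Phenotype model

The five phenotypes are generated with a Gaussian copula. A latent vector
z ~ N(0, L) is transformed marginal-by-marginal: an affine map for sleep
hours (mean 6.8 h — the cohort's median split value — sd 1.1 h), threshold
discretisation for the ordinals (insomnia and dozing on 0–3, PHQ-2 on 0–6
with P(PHQ-2 ≥ 3) ≈ 3%, matching the prevalence of the "depressed" stratum
in a general-population imaging cohort), and a rounded affine map for the
symbol-digit cognition count (mean 19, sd 5, floored at 0).

Discretisation attenuates Pearson correlations, so the latent matrix L is
*calibrated*: a fixed-point iteration adds the residual error between the
target partial correlations and the realised (covariate-adjusted,
Monte-Carlo, n = 80,000 per iteration) partial correlations to L, projects
back to a positive-definite correlation matrix (eigenvalue clip at 1e-6),
and stops when the maximum error falls below 0.004 or after 12 rounds. The
calibration uses its own fixed internal random stream and is cached per
coupling spec, so generated tables remain a deterministic function of the
caller's seed. Realised partial correlations match the targets within
±0.01 at n = 100,000 (verified in the suite).

Covariates (age, sex, site, SES, education, ethnicity, accelerometry time
offset, head motion, task performance statistics) are drawn independently
with fixed plausible distributions; an optional leakage term adds covariate
effects on the latent scale (default zero), and the calibration measures
partial correlations under whatever leakage is configured, so adjustment
behaviour is testable.

## Task data and decoding

The default block design has 20 blocks (10 face, 10 shape; the seven
stimulus categories cycle within class so each occurs at least twice), 6
volumes per block split into 3 samples of 2 averaged volumes — exactly 60
balanced samples — with 4-volume rest gaps, TR 0.735 s, and the response
placed 5 volumes (3.675 s) after block onset. The within-run ordering of
categories is not constrained by the emulated protocol beyond the sample
count; the alternating default is one concrete choice.

Each region carries fixed face/shape patterns (unit-variance Gaussian
vectors, plus a 0.3-sd category-specific perturbation for RDM structure).
The planted amplitude for subject s and region g is
a_sg = max(0, a0_g + Σ_k c_k z_k(s)) with a0_g ~ U(0.05, 0.30) and default
couplings c: sleep +0.05, cognition +0.025, insomnia −0.015, PHQ-2 −0.04,
dozing 0 (per SD of phenotype). The floor encodes that separability cannot
be negative. Defaults produce region accuracies of roughly 0.55–0.80,
increasing monotonically in a_sg.

Noise is AR(1) per voxel plus a slow sinusoid (0.5–1.5 cycles/run, random
phase) over a baseline of 100, so detrending and percent-signal-change have
real structure to remove. **Noise-scale tradeoff:** the decoding protocol
assigns the 60 samples to 6 folds at the sample level. Noise that is
correlated between samples of the same block then leaks across folds and
biases zero-signal accuracy above chance (~53–54% at AR coefficient 0.3).
The defaults (AR 0.1, drift amplitude 0.5, noise sd 1) keep 2-volume-
averaged samples approximately exchangeable, so the zero-signal null decodes
at 50% ± 2%. Real fMRI has stronger temporal autocorrelation; with such
data a block-wise fold assignment would be required for an unbiased null,
which the fixed 60-sample/6-fold scheme does not accommodate. This is a
limitation of what the chance-calibration result shows about real data.

Decoding canonicalises sample order (lexicographic sort) before the seeded
stratified fold assignment, so accuracy is exactly invariant to input
permutation. Two linear-SVM backends solve the same soft-margin problem
(C = 1 by default): a numba dual coordinate-descent solver (the liblinear
algorithm, bias as an augmented feature) used for cohort-scale simulation,
and scikit-learn's libsvm SVC kept as the independent reference; the suite
checks their mean-accuracy agreement. The two differ only in intercept
regularisation, which moves a handful of test predictions per fold on
near-chance data.

## Resting connectivity

Subject edge vectors are built on the Fisher-z scale — base edge pattern
N(0.15, 0.15), a uniform global shift per phenotype SD
(rest_global_coupling), a *shared* spatial edge profile (from Gaussian
region loadings) scaled per phenotype (rest_edge_coupling), and N(0, 0.25)
noise — then mapped through tanh into (−1, 1). The shared profile is what
gives different phenotypes *correlated* edge-level signatures, which is the
quantity the signature-correlation stage measures; the global shift is what
the brain-wide mean analysis detects. Default signs plant the headline
phenomenon: task amplitude rises with sleep and falls with depression/
insomnia, while rest connectivity rises with all three (dozing negative in
both). The 21-IC edge family is generated by the same scheme. Voxel-level
dual regression is replaced by region-level correlation throughout: the
downstream analyses consume only region-by-region values, and the
diagonal-normalisation step is preserved for non-unit-diagonal inputs.

## Inference conventions

* Partial correlation: Pearson r of OLS residuals; exact beta null with
  n_eff = n − k − 2; Fisher-z CIs at 99% (α = 0.05 over five phenotypes);
  complete-case per pair; one-hot categoricals dropping the reference
  level; education ordinal by default (categorical via a switch).
* Association maps: phenotypes standardised before fitting so betas are
  comparable across phenotypes; task maps add β/max(1 − accuracy,
  1/(2·60)) — the floor keeps perfectly decoded regions finite. Task
  models adjust for task performance statistics; thickness models drop
  head motion and task statistics; the accelerometry offset enters only
  for the sleep phenotype; imaging models include a sex×age interaction.
* Multiplicity: BH within each phenotype's map, compared to 0.05/5;
  Bonferroni for edges with the universe defaulting to 5 × #edges (an
  explicit m reproduces other conventions, e.g. 5 × 21 components).
* Spin test: per permutation, one uniform SO(3) rotation applied to left
  centroids and its x-mirrored version to right centroids; each original
  region takes the value of the nearest rotated centroid (duplicates
  allowed); the two hemisphere reassignments are averaged because regions
  are bilateral merges; p = count(|r_perm| ≥ |r_obs|)/n_perm with no +1
  term, following the percentage-of-permutations definition (ties use ≥).
  A plain label-permutation scheme is available behind a flag. Measured
  size on smooth mirror-symmetric nulls is ≈ 0.055 at α = 0.05, versus
  0.3–0.6 for the parametric test.
* Dual-criterion significance for region-based signature pairs: both
  p_beta and p_spin below α/5.
* CPM: full-sample covariate residualisation by default, mirroring the
  stated protocol order — this leaks covariate fits across folds, and a
  within-fold option is provided and recommended for real use. Edge
  selection is strict (p < 0.01); selected edges are averaged into a
  single signed feature (the classic positive/negative-network split is
  out of scope); out-of-fold predictions are pooled before computing
  performance r. A fold with no selected edge predicts its training mean
  and is reported.

## Problem sizes

The suite runs every stage at desk scale: decoding cohorts of 50 × 20
(null calibration) and 500 × 12 over 25 seeds (sign recovery), phenotype
calibration checks at n = 30,000 and 100,000, spin calibration at 64
regions × 2000 replicates × 100 rotations, CPM nulls at 500 × 190 over 100
seeds, and an end-to-end pipeline at 200 subjects × 8 regions. These sizes
were chosen so the full chain exercises the same code paths as a
population-scale run while remaining reproducible on a single CPU.

## Limitations

* The generator emulates statistical structure, not physiology: no
  hemodynamic response shape, no physiological noise, no spatial voxel
  correlation within regions, no site or motion artefacts beyond the
  covariate columns. Passing tests show the *analysis chain* is correct and
  calibrated under the planted model, not that the scientific findings
  generalise.
* Thickness values and their couplings are synthetic throughout.
* The PHQ-2 stratified reanalysis needs ≳ 1,000 subjects before the
  depressed stratum (≈ 3% prevalence) can support the edge models; the
  pipeline logs and skips the split below that.
* IC spatial maps are not modelled, so percentile-based component
  membership rules have no counterpart here.
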