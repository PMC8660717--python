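# Methods

## Problem and data model

Patients with low/intermediate-risk prostate cancer on active
surveillance are followed with serial multiparametric MRI. Each
analysis unit is a target lesion with a tumour ROI segmented on a
baseline and a final scan in two modalities (T2-weighted and ADC).
The outcome is binary histopathological progression (grade-group
increase on repeat targeted biopsy). The pipeline asks whether the
change in intratumoural texture between the two scans predicts
progression, and benchmarks it against the radiologist-assigned
PRECISE change score (1–5, dichotomised at ≥ 4).

No image data are distributed with the package; all computations run
on synthetic cohorts (below) that reproduce the statistical structure
the analysis assumes. The default cohort shape is 27 progressors and
38 non-progressors (65 lesions), the configuration with which the
published summary metrics of the target study are arithmetically
consistent.

## Texture extraction

Features are computed in 3D over the full ROI, without resampling and
without re-segmentation. Grey levels are discretised with a **fixed
bin number**: the ROI's own min–max range is split into `n_bins`
equal-width bins, `level = floor(n_bins·(x − min)/(max − min)) + 1`,
with the maximum mapping to `n_bins`. This is the IBSI-recommended
choice for arbitrary-unit modalities such as MRI; bin edges are never
taken from a global calibration. A constant-intensity ROI maps to a
single level (level 1) by convention.

Six feature classes are implemented (81 features by default):
first-order statistics, grey-level co-occurrence (GLCM), run length
(GLRLM), size zone (GLSZM), dependence (GLDM) and neighbourhood grey
tone difference (NGTDM). Conventions that the field leaves open and
this package fixes:

* Directional matrices (GLCM, GLRLM) use the 13 unique offsets of the
  26-connected 3D neighbourhood; feature values are computed per
  direction and **averaged across directions**. Co-occurrence matrices
  are symmetrised and normalised per direction before feature
  computation.
* GLSZM zones use 26-connectivity; GLDM dependence counts use the 26
  neighbours with level-difference tolerance α = 0, and the dependence
  size is stored as count + 1 so that inverse-square emphases remain
  finite for isolated voxels.
* Degenerate single-level ROIs: matrix features that would divide by a
  zero level variance (e.g. GLCM correlation, NGTDM contrast) return
  0 with a warning, keeping feature vectors finite for the robustness
  stage. Single-voxel ROIs yield defined first-order values and
  degenerate-but-finite matrix features.
* First-order variance/skewness/kurtosis use population moments;
  entropy and uniformity are computed on the discretised histogram.

ROI perturbation uses scipy binary opening and closing with a 3×3×3
box structuring element by default. Closing is applied on a padded
grid so that it is extensive (mask ⊆ closing) also at the array
border. A perturbation that empties the mask is flagged and the
affected replicate is skipped with a log entry rather than poisoning
the ICC.

## Robustness filtering

For each feature, modality, time point and bin count, the three mask
variants (original/opened/closed) are treated as k = 3 replicate
measurements across lesions and summarised by an intraclass
correlation coefficient. The default variant is **two-way mixed
effects, single rater, consistency** — ICC(3,1) = (MS_R − MS_E) /
(MS_R + (k − 1)·MS_E) — because the perturbation modes are fixed
"raters" and a systematic offset introduced by morphology alone
should not count against robustness. One-way random and absolute
agreement variants are available via configuration. If all cells are
identical the ICC is 1 by convention (logged). The implementation is
cross-checked in the tests against an independent mean-squares oracle
and against `pingouin.intraclass_corr`.

A feature is *robust* iff ICC > 0.8 (strict) and enters the modelling
set only if robust at **both** time points. The working bin count
maximises the total robust-feature count over the grid
{8, 16, 32, 64, 128, 256}; ties are broken towards the larger bin
count by default, with a smallest-of-tied policy available (on the
published totals, where 128 and 256 bins tie at 214 robust features,
the two policies give 128 and 256 respectively; the package does not
presume which the original analysts intended).

The acquisition screen computes Spearman's ρ between each baseline
feature and each available acquisition scalar, flagging p < 0.05
without multiplicity correction. Flagged features are reported, not
silently dropped; exclusion is a configuration choice. The time point
used for screening is configurable (baseline by default).

## Delta modelling

Δf = f_final − f_base per robust feature; T2WI- and ADC-derived
deltas are concatenated into one matrix (a per-modality mode is a
configuration switch). Any per-sample additive offset common to both
time points cancels exactly — the core premise of delta features —
and the synthetic generator includes such offsets precisely so the
tests can assert the cancellation.

**Parenclitic network.** For every unordered feature pair an RBF-SVM
(C = 1, `gamma="scale"`, inputs standardised on training statistics,
matching the classical SVM defaults) is trained on the two-column
submatrix vs outcome, with a Platt-style sigmoid fitted on the
training decision values to give probabilistic edges. A sample's
network has features as vertices and edge weights
p_ij ∈ [0, 1]; the read-out is the mean vertex degree
2·Σ_{i<j} p_ij / p ∈ [0, p − 1], mapped to a probability by a
binomial GLM with logistic link (statsmodels; an unpenalised logistic
fallback handles perfectly separated degrees). Pair classifiers and
the GLM are refitted inside every cross-validation fold. Note that
the degree→outcome GLM is fitted on in-sample degrees; because pair
SVMs partially memorise training labels, its in-sample slope p-value
is optimistic and only out-of-sample quantities (LOOCV probabilities)
should be interpreted — the tests verify the null behaviour out of
sample.

**LASSO.** L1-penalised logistic regression; the penalty is chosen by
5-fold stratified cross-validation *within the training fold*
(log-loss criterion, 12-point log-spaced grid), with standardisation
statistics likewise computed on the training fold only, preserving
LOOCV validity.

**Random forest.** 500 trees, maximum depth 10, `random_state=42`
(configurable), per the modelling settings of the target study.

## Evaluation

LOOCV produces one out-of-fold probability per sample; each fold's
model is fitted without the held-out sample, and the tests include a
leakage oracle (flipping the held-out label must not change its own
prediction). Binary metrics use a 0.5 probability threshold (the
original operating point is not published; the threshold is a
parameter). Conventions per metric:

* **AUC** — tie-corrected rank statistic; 95% CI and paired
  comparisons by DeLong's structural-components method (implemented
  from scratch, cross-checked against `pROC` and against a
  20,000-replicate paired permutation oracle in the tests); identical
  score vectors give z = 0, p = 1 by convention.
* **Sensitivity/specificity** — stratified non-parametric bootstrap,
  percentile method, 2,000 replicates, point estimates from the
  original data.
* **PPV/NPV** — Wald intervals on the proportion scale clipped to
  [0, 1]; undefined when the denominator is empty.
* **Confusion-matrix reconstruction** — given printed sensitivity and
  specificity percentages and class counts, searches for the unique
  integer TP and TN whose ratios round (half-up, one decimal) to the
  printed values; zero or multiple candidates raise an error, which
  is exactly the signal that a printed value and a denominator are
  inconsistent.

## Synthetic cohorts

*Feature mode* draws baseline vectors from a multivariate Gaussian
with equicorrelation ρ (default 0.3) plus a per-sample N(0, 1) shared
intercept; final = baseline + N(0, 1) delta noise + a shift of
`effect_size` (in delta-noise SD units, i.e. a standardised mean
difference) on the informative features in progressors only. Defaults:
20 features, 4 informative, effect size 1.0 — a moderate, realistic
imaging-biomarker effect chosen once; the target study publishes no
quantitative effect sizes, so these are free parameters of the
simulation, not estimates of the study's data. Perturbation
replicates for the robustness stage add independent noise
(`noise_sd_perturbation`) to a designated "fragile" feature subset
and near-zero jitter elsewhere.

*Image mode* builds ellipsoidal lesions (radius 3–5.5 voxels in a
28×28×16 grid by default) on smooth backgrounds; lesion texture is a
Gaussian random field with per-sample contrast and autocorrelation
length. In progressors only, the final scan's contrast (+60%) and
correlation length (+50%) drift and the ADC-like in-lesion mean drops
by 250 units; non-progressor parameters are identical at both time
points up to a shared noise realisation (70% shared variance).
Simulated PRECISE scores give progressors {4, 5} and non-progressors
{1, 2, 3} with probability 1 − `reader_error_rate` (default 0.2),
flipped otherwise.

What the generator does **not** emulate: MR physics, bias fields,
inter-scan registration error, multi-lesion patients, scanner
heterogeneity, or any real relationship between texture drift and
histology. Passing tests therefore demonstrate the correctness and
internal calibration of the pipeline — not clinical performance on
real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk
scale: feature-mode cohorts of 60–65 samples with 8–20 features,
image-mode cohorts of ~10 lesions at two bin counts. Parenclitic
training cost grows as C(p, 2) pair SVMs per fold, which is why the
null-calibration suite uses 10 features and the default cohort 20.
The null-calibration check asserts the per-model *mean* LOOCV AUC
over 5 seeds within [0.3, 0.7]; a single-seed null AUC at n = 60 has
a standard error of ≈ 0.075, so the mean is the stable quantity.

Seeds: every stochastic component takes an explicit seed; the
pipeline derives stage seeds from one run seed and records the
effective configuration alongside every output, so identical
configurations reproduce outputs byte for byte.

## Known limitations

* The published robust-feature counts and AUCs of the target study
  depend on its unavailable MRI data and cannot be recomputed here;
  only the printed-table arithmetic (PPV/NPV from
  sensitivity/specificity and class counts) is exactly reproducible.
* The texture-feature roster is the package's own IBSI-style set; the
  original feature list is configuration-dependent, so the class
  roster is config-driven rather than hard-coded.
* Platt calibration on training decision values slightly overfits
  edge probabilities on small folds; an alternative calibration can
  be swapped in via the pair-model hook without touching the network
  read-out.
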