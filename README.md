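# deltarad

Delta-radiomics modelling of prostate-cancer progression on active
surveillance (AS). Patients on AS are monitored with serial MRI; the
question is whether the *change* in quantitative texture of a tumour
region of interest (ROI) between a baseline and a later scan predicts
histopathological progression, and how such models compare with the
radiologist-assigned 5-point PRECISE change score (dichotomised at
≥ 4 = radiological progression).

The package implements the full analysis pipeline for a two-class
cohort of paired scans (progressors vs non-progressors):

1. **Texture extraction** (`deltarad.features`) — 3D first-order,
   GLCM, GLRLM, GLSZM, GLDM and NGTDM features over a tumour ROI with
   fixed-bin-number quantisation (equal-width bins over the ROI's own
   min–max range, no resampling, no re-segmentation), directional
   matrices averaged over the 13 unique 3D directions.
2. **Robustness filtering** (`deltarad.robustness`) — each feature is
   re-measured after morphological perturbation of the mask
   (binary opening and closing, treated as k = 3 replicate "raters")
   and retained only if its two-way mixed-effects consistency ICC
   exceeds 0.8 at **both** time points; the working bin count is the
   one maximising the total robust-feature count; a Spearman screen
   flags features associated with acquisition parameters.
3. **Delta modelling** (`deltarad.modeling`) — for each robust feature
   Δf = f_final − f_base; classifiers on the delta matrix:
   * a **parenclitic network**: an RBF-kernel SVM per feature pair,
     a per-sample graph whose edge weights are the pairwise predicted
     progression probabilities p_ij, the mean vertex degree
     2·Σ_{i<j} p_ij / p as read-out, and a binomial GLM mapping degree
     to outcome;
   * **LASSO logistic regression** (inner-CV penalty choice);
   * **random forest** (500 trees, depth 10, seed 42).
4. **Evaluation** (`deltarad.evaluation`) — leave-one-out
   cross-validation; AUC with DeLong confidence intervals and paired
   DeLong tests; sensitivity/specificity with stratified percentile
   bootstrap (2,000 replicates); PPV/NPV with Wald intervals; and
   reconstruction of integer confusion matrices from printed
   sensitivity/specificity percentages.
5. **Synthetic cohorts** (`deltarad.synthetic`) — no MRI data are
   shipped; paired-scan cohorts (27 progressors / 38 non-progressor
   lesions by default) are generated either as feature tables with a
   configurable number of informative delta features, or as 3D
   T2WI-like / ADC-like volumes whose lesion texture drifts in
   progressors only.

## Worked example

The numbered drivers under `analysis/` run the stages in order
(`python analysis/01_simulate_cohort.py`, …). The whole pipeline also
runs as one command:

```bash
deltarad demo --seed 42 --out run/
```

which simulates the default cohort, filters features by ICC, fits all
three models under LOOCV and prints the summary table. With seed 42
the model stage reports

```
parenclitic  LOOCV AUC = 0.698
lasso        LOOCV AUC = 0.844
rf           LOOCV AUC = 0.794
precise      LOOCV AUC = 0.718
```

i.e. on a cohort with a moderate simulated effect (standardised delta
shift of 1.0 on 4 of 20 features) the delta-feature models and the
simulated reader scores all discriminate progressors from
non-progressors at AUCs in the 0.70–0.85 range, with pairwise DeLong
tests distinguishing the strongest model (LASSO, AUC 84.4%,
CI 74.6–94.2%) from the parenclitic network on this particular seed
(p = 0.008). The same evaluation stage reconstructs the published
summary table of the study population this pipeline targets: from
printed sensitivity/specificity pairs and the 27/38 class counts it
recovers the unique integer confusion matrices (e.g. sensitivity
74.1% → TP = 20 of 27) and reproduces every printed PPV/NPV cell
exactly (90.9/83.7, 69.7/87.5, 76.0/80.0, 65.8/92.6 percent).

Python API in brief:

```python
import deltarad as dr

cohort = dr.generate_feature_cohort(dr.CohortConfig(seed=1))
dm = dr.delta_matrix(cohort.base, cohort.final, cohort.outcome)
probs = dr.loocv(dm.X.to_numpy(), dm.y, dr.get_model("parenclitic"))
auc, ci = dr.delong_ci(probs, dm.y)
```

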