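# asradiomics

A tested, reusable reimplementation of an MRI-radiomics workflow for
**baseline prediction of prostate-cancer progression on active surveillance
(AS)**. Nearly half of AS patients drop out within five years, many because
their tumour progresses; the clinical question is whether quantitative
texture and shape features extracted from the baseline T2-weighted (T2WI)
and apparent-diffusion-coefficient (ADC) MRI of the visible lesion add
predictive value over standard clinical markers (PSA, gland volume, PSA
density, Likert score, grade group, zone).

The package implements the complete pipeline:

1. **Synthetic cohort** — the original patient data are not public, so a
   phantom generator produces a two-arm cohort (default 35 progressors vs
   38 stable lesions) of superellipsoid lesions with Gaussian-random-field
   texture, planted group effects, clinical covariates and single-scanner
   acquisition metadata. Every downstream stage is therefore testable
   offline.
2. **ROI perturbation** — morphological opening and closing with a 7-voxel
   spherical structuring element (radius 1) emulate inter-reader contouring
   variability, giving three versions of each lesion mask.
3. **Feature extraction** — 107 IBSI-style features per configuration:
   18 first-order, 14 3D shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM,
   5 NGTDM. Computation is 3D on the voxel lattice with fixed-bin-count
   discretisation over the ROI intensity range (no resampling, no
   resegmentation). Three mask versions x six bin counts
   {8, 16, 32, 64, 128, 256} = 18 configurations per sequence.
4. **Calibration** — feature robustness across mask versions is scored with
   the intraclass correlation coefficient

   `ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)`

   (two-way mixed model, consistency, single measurement; k = 3 mask
   versions). Features with ICC > 0.8 are "highly robust"; the operating
   bin count maximises the combined (T2WI + ADC) robust count.
5. **Acquisition decoupling** — robust features are screened against six
   acquisition parameters (TE, TR, flip angle, slice thickness, spacing
   between slices, pixel spacing) by Spearman correlation; a feature with
   p < alpha for any parameter is removed.
6. **Feature selection** — six filter methods (Fisher score, t-score,
   Wilcoxon rank-sum, Gini index, mutual-information maximisation, mRMR),
   keeping the top 5 (clinical), 10 (single-sequence radiomic) or 15
   (combined) features.
7. **Predictive modelling** — leave-one-out cross-validation of six
   classifiers (KNN, logistic regression, LDA, elastic-net logistic
   regression, SVM, random forest) over seven feature sets, with per-fold
   standardisation, per-fold selection and per-fold hyperparameter tuning.
   AUC = Mann-Whitney statistic, 95% CI by DeLong; sensitivity/specificity
   trade-off tables at specificity (and sensitivity) targets 0.70-0.90.

## Worked example

```python
from asradiomics import PhantomConfig, run_experiment

manifest = run_experiment(
    PhantomConfig(seed=1),                 # 35 + 38 lesions, planted effects
    selectors=("WLCX", "FSCR"),            # reduced grid for speed
    classifiers=("LG", "LDA"),
)
print(manifest["selected_n_bins"])
grid = manifest["artifacts"]["grid"]
print(grid[grid.feature_set.isin(["clinical", "clinical+t2w"])]
      [["feature_set", "selector", "classifier", "auc"]])
```

On the default synthetic cohort (seed 1) this prints a selected bin count
of 8 — the smooth phantoms are robust at every bin setting, so the tie rule
picks the smallest — and a grid in which the clinical-only panel tops out
at AUC ≈ 0.58 while adding T2WI radiomics raises the maximum to ≈ 0.77:

```
     feature_set selector classifier       auc
0       clinical     WLCX         LG  0.553383
...
16  clinical+t2w     WLCX         LG  0.766917
18  clinical+t2w     FSCR         LG  0.768421
```

That clinical-to-combined improvement is the planted synergy the generator
encodes: moderate PSA / PSA-density shifts plus texture and size effects
that only the radiomic features can see.

The same pipeline is scriptable from the shell:

```bash
asrad simulate out/phantoms --seed 1        # NIfTI volumes + cohort.csv
asrad run out/experiment --seed 1           # full pipeline, all artifacts
```

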