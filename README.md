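# sspkrecur

Quantitative DCE-MRI pharmacokinetics and recurrence-prediction statistics
for breast cancer treated with neoadjuvant chemotherapy (NACT).

## The problem

Patients with residual disease after NACT are at elevated risk of recurrence,
but clinicopathological predictors (residual cancer burden, age, stage,
receptor status) are only partly informative — and residual cancer burden is
known only after surgery. Quantitative dynamic contrast-enhanced (DCE) MRI
measures tumor microvascular physiology before and after NACT and may add
predictive signal. This package implements, as a tested and reusable
pipeline, the two halves of that analysis:

1. **Shutter-Speed (FXR) pharmacokinetic modelling** of voxelwise DCE-MRI
   time-courses, estimating the transfer rate constant *K*<sup>trans</sup>
   (min⁻¹), the extravascular-extracellular volume fraction *v*<sub>e</sub>,
   and the mean intracellular water lifetime *τ*<sub>i</sub> (s), with
   *k*<sub>ep</sub> = *K*<sup>trans</sup>/*v*<sub>e</sub> derived; plus
   variable-flip-angle *T*<sub>10</sub> mapping, a parametric population
   arterial input function, and RECIST longest-diameter morphometry.
2. **Small-cohort recurrence statistics**: pooled-variance t-tests and exact
   tests for group comparisons, univariable C statistics with DeLong
   confidence intervals, Firth penalized logistic models with backwards
   stepwise AIC selection, Youden operating points with exact binomial
   intervals, PC1 augmentation, paired DeLong AUC comparison, repeated
   stratified cross-validation, univariable Cox models and precision-recall
   curves.

Because the underlying patient data are not publicly distributable, the
package ships a **synthetic cohort generator** calibrated to the published
cohort margins (47 patients, 7 recurrences = 14.9%, 27 HR-positive,
24 HER2-positive, 8 triple-negative) and to the published group-wise MRI
metric means/SDs. It emits voxel-level dynamic studies that follow the FXR
forward model exactly, so every downstream stage runs — and can be validated
against ground truth — without any download.

## The model

A spoiled-gradient-echo frame measures

S = s₀ · sin α · (1 − E)/(1 − cos α · E),  E = exp(−TR·R₁),

and the observed longitudinal rate under fast-exchange-regime (FXR) water
exchange is the slowly relaxing eigenvalue of the two-site exchange matrix

2R₁L = (R₁i + R₁e + k_ie + k_ei) − √((R₁i + k_ie − R₁e − k_ei)² + 4 k_ie k_ei),

with R₁e = R₁0 + r₁·C_t(t)/v_e, R₁i = R₁0, k_ie = 1/τ_i,
k_ei = k_ie (1 − v_e)/v_e, and the tissue concentration from standard Tofts
kinetics, C_t(t) = K^trans ∫₀ᵗ C_p(u) e^{−k_ep(t−u)} du. Estimation is
bounded least squares on (K^trans, v_e, τ_i) from a fixed 3×3×3 start grid,
with s₀ fixed from the pre-injection baseline.

## Worked example

```python
from sspkrecur import (AcquisitionParams, AIFModel, PKParams,
                       fxr_forward_timecourse, fit_voxel_fxr)

acq, aif = AcquisitionParams(), AIFModel()
truth = PKParams(ktrans=0.14, ve=0.54, tau_i=0.78)
signal = fxr_forward_timecourse(truth, t10=1.4, acq=acq, aif=aif, s0=1000.0)
print(fit_voxel_fxr(signal, 1.4, acq, aif).summary())
```

prints

```
Shutter-Speed (FXR) voxel fit
  Ktrans     0.14000  1/min
  ve         0.54000
  tau_i      0.78000  s
  kep        0.25926  1/min  (Ktrans/ve)
  s0        1000.000
  ||r||   4.6896e-13
  converged: True (best of 27 starts, index 14)
```

i.e. the noiseless forward curve refits to the generating parameters
(residual at machine precision), with the efflux rate constant
k_ep = 0.14/0.54 = 0.259 min⁻¹ derived rather than fitted.

A full synthetic study — cohort, imaging, voxel fits, metric table, and the
report tables (group comparisons and model performances) — runs from the
command line:

```bash
sspkrecur all --run-dir runs/demo --seed 0
```

which writes `cohort.csv`, `truth.csv`, per-visit NIfTI volumes,
`metrics.csv`, `group_comparisons.csv` (15 MRI-metric rows: group means/SDs, t-test p,
univariable C statistic with DeLong CI), `model_performance.csv` (Firth model AUCs with
cross-validated AUCs and paired DeLong p-values) and `manifest.json`.

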