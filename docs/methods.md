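# Methods

This note records the models implemented, the conventions and defaults
chosen where the design was genuinely open, and what the synthetic data do
and do not establish.

## Signal model and relaxometry

Dynamic frames are modelled as steady-state spoiled gradient-echo (SPGR)
signal, S = s₀ sin α (1 − E)/(1 − cos α E) with E = exp(−TR·R₁). Defaults
follow the acquisition the pipeline emulates: dynamic flip angle 10°,
TE/TR = 2.9/6.2 ms, a proton-density-weighted companion volume at 5° and
TR = 50 ms, 28–38 frames at 14–20 s spacing, contrast injection at the start
of the third frame. The TE/T2\* factor is treated as constant and absorbed
into s₀; it cancels exactly in the T1-mapping ratio and is neglected
post-contrast.

**Native T1 mapping.** Per voxel, the ratio of the second-baseline dynamic
frame to the proton-density frame (in which s₀ cancels) is inverted for R₁0
by bracketed Brent root finding on R₁ ∈ [0.05, 20] s⁻¹ (T₁0 from 20 s down
to 50 ms, far beyond the physiological range). The ratio is monotone in R₁
over the bracket; voxels with non-positive intensities or ratios outside the
attainable range are flagged invalid and excluded from ROI summaries.

**Arterial input function.** The cohort-mean measured AIF behind the
original analysis is not distributable. The package uses the standard
Parker-form parametric population AIF (two Gaussian bolus passes plus a
sigmoid-modulated exponential washout) with its literature parameters and
hematocrit 0.45, which is the conventional stand-in when acquisition,
agent, dose and injection protocol are fixed. Bolus arrival defaults to the
injection-frame start (zero delay, configurable). Contrast relaxivity
defaults to 3.7 s⁻¹·mM⁻¹, a representative value for a macrocyclic
gadolinium agent at 3 T (configurable; the source acquisition documents
agent and field but not relaxivity).

**Kinetics.** Tissue concentration follows standard Tofts kinetics. The
convolution treats C_p as piecewise linear and integrates each segment in
closed form (an IIR recursion on uniform grids), so it is exact for
piecewise-linear inputs; the forward model evaluates it on an internal 1 s
grid and interpolates at frame times. Time origin is the injection-frame
start.

**Water exchange (FXR).** The observed rate is the slowly relaxing
eigenvalue of the two-site exchange-relaxation matrix with unit apparent
population — the canonical fast-exchange-regime simplification. Water
population fractions are approximated by volume fractions (p_i = 1 − v_e,
p_e = v_e), and the intracellular rate is set to the pre-contrast R₁0
(well-mixed pre-contrast assumption). At C_t = 0 the eigenvalue reduces to
R₁0 algebraically; as τ_i → 0 it approaches the linear relation
R₁0 + r₁C_t with a residual of order p_i p_e (r₁C_t/v_e)² τ_i. That
quadratic growth in concentration is why the fast-exchange-limit equivalence
checks run on the tumor-mean physiological range (K^trans ≤ 0.2 min⁻¹,
v_e 0.4–0.8); at K^trans ≈ 0.5 min⁻¹ the exchange correction itself exceeds
0.1% of baseline signal, which is a property of the model, not an
implementation error.

## Estimation

Per voxel, bounded least squares (trust-region reflective) minimizes the sum
of squared signal residuals over (K^trans, v_e, τ_i) with bounds
[0, 5] min⁻¹, [0.01, 1], [0.05, 5] s. The signal scale s₀ is fixed from the
pre-injection baseline mean (whether the original analysis fitted or fixed
s₀ is unstated; fixing is the default here and makes the baseline exact).
A fixed 3×3×3 start grid (K^trans ∈ {0.02, 0.1, 0.5}, v_e ∈ {0.2, 0.5, 0.8},
τ_i ∈ {0.2, 0.6, 1.5}) guards against local minima; the lowest residual
wins, ties broken by grid order, and voxels where no start converges are
flagged and excluded from ROI means. k_ep = K^trans/v_e is derived, never
fitted, and ROI summaries average each parameter voxelwise — k_ep as the
mean of voxel ratios, which is not the ratio of means.

Measured performance (recomputed by `scripts/acceptance.py`): noiseless
round trips recover the generating parameters to ≪1%; at baseline SNR 20
the median |relative error| of K^trans is ≈13–15% (the error distribution is
broad — quartiles roughly 6% and 24% — so a median over a few hundred voxels
still moves by a point or two between noise realizations).

## Morphometry

RECIST longest diameter is measured in-plane per axial slice as the largest
center-to-center distance among mask voxels plus one in-plane voxel size, so
a single voxel reports its extent rather than zero. Percent changes are
fractions, (V4 − V1)/V1, undefined (missing) when the baseline is not
positive. For post-treatment studies with no enhancing tumor, three
consecutive central slices of the mid-treatment ROI are copied to a stated
slice of the final-visit grid, and size metrics for such cases are
computed on the transferred ROI (callers record the substitution per
patient). The synthetic generator always emits enhancing tumors, so this
path is exercised by unit tests rather than the simulated pipeline.

## Statistics

- **Firth logistic regression** maximizes l(β) + ½ log det I(β) by
  modified-score Newton iterations with step-halving (convergence when the
  largest modified-score component < 1e-8, cap 100 iterations). Inference is
  Wald, from the inverse Fisher information at the optimum. Collinear
  design columns are dropped with a warning.
- **Model selection** is backwards stepwise by AIC over Firth main-effects
  models, ties broken by candidate order. AIC uses the *unpenalized*
  log-likelihood at the Firth estimates: the Jeffreys penalty grows by about
  ½ log(n·w̄) per design column, which would exceed AIC's 2-per-parameter
  charge and make backward elimination inert, so including it in the
  selection criterion would defeat the procedure.
- **Discrimination** is the Mann–Whitney C statistic (ties 0.5), with DeLong
  placement-value variance for CIs (Wald, clipped to [0, 1]) and the paired
  DeLong z-test for AUC comparisons. Operating points maximize Youden's J
  over observed-score midpoints, ties toward higher specificity;
  sensitivity, specificity and PPV carry Clopper–Pearson exact intervals.
- **Cross-validation** is repeated stratified 5-fold (100 repeats by
  default; repeat count was unstated in the source design) with pooled
  out-of-fold linear predictors per repeat; pooled scoring is the default,
  flagged as a convention. Under a pure-noise predictor the mean cv AUC is
  centered on 0.5 (a single n = 200 cohort has SD ≈ 0.045, so calibration
  checks average over cohorts).
- **Cox** univariable models use the Breslow partial likelihood
  (statsmodels PHReg). **PC1** comes from the correlation-matrix
  eigendecomposition of the standardized metric block, sign fixed so the
  post-treatment K^trans loading is positive. Exact tests: hypergeometric
  point-probability rule for 2×2, Freeman–Halton enumeration for 2×K.
  Residual cancer burden enters models as an ordinal 0–3 code (1 df — a
  deliberate economy at 47 patients and 7 events); stage can be coded
  ordinally or categorically via configuration. All p-values are nominal.

## Synthetic cohort

The generator's defaults are the study conditions: 47 patients with exactly
7 recurrences (14.9%), receptor-subtype cells realized exactly
(27 HR-positive, 24 HER2-positive, 8 triple-negative), group-wise RCB and
age distributions, and group-wise lognormal distributions for LD, K^trans,
v_e and τ_i at both visits, moment-matched to the published means/SDs
(lognormal respects positivity; only means/SDs are published). Parameters
are coupled by a Gaussian copula whose default correlations (moderate
positive K^trans couplings within and across visits, weak elsewhere) are a
modelling choice — no joint distribution is published. v_e draws are capped
at 0.99 (shifts the configured mean by ~1% at the largest published spread).

Recurrence probability follows a logistic effect model on log K^trans at V4,
RCB and age. In the default fixed-margin mode, distribution groups are
assigned with exact counts, parameters are drawn conditional on group, and
the recurrence label goes to the top-7 effect-model probabilities; labels
therefore agree with the generating group only up to the overlap of the
group distributions, and calibration checks compare against the recorded
generating group — the quantity the configuration actually parameterizes. A
sampled mode draws Bernoulli labels instead. Times to recurrence are
exponential with median 5 months; censoring follow-up is lognormal with
median 85.5 months. Stage probabilities and the censoring spread are
invented plumbing (no published values).

Imaging: ellipsoidal ROIs on a configurable grid (defaults 1 mm in-plane,
1.4 mm slices), voxel-level multiplicative lognormal jitter (CV 20%) around
patient-level parameters, FXR forward signal plus i.i.d. Gaussian noise on
the signal scale (not Rician: fitting is least squares and high-SNR breast
DCE is near-Gaussian), and a co-registered proton-density volume with the
companion settings. The generator does not simulate k-space acquisition,
view sharing, coils, motion, or realistic spatial texture — so passing
tests establish estimator correctness under the stated model, not
robustness to acquisition artifacts.

## Problem sizes

The demo pipeline runs 12 patients on a coarse 3 mm grid with a 30-voxel
fit cap and a 2×2×2 start grid; the full-resolution defaults (1.4 mm slices,
3×3×3 starts, every ROI voxel) are library defaults intended for real-scale
runs. The acceptance script uses a 3×3×3 noiseless round-trip grid,
300 noisy voxels at SNR 20, 10,000 bootstrap replicates for the DeLong
check, 10 null cohorts × 20 CV repeats, 1,000 Cox null replicates,
200 simulated cohorts for the AUC-gain comparison, and a 10-patient
end-to-end run at SNR 50 — sizes chosen so the whole script completes in a
few minutes on one CPU while keeping Monte-Carlo error well inside each
quantity's interpretation band.

## Known limitations

- Only the first-generation FXR model is implemented (no vascular water
  exchange compartment, no individual AIF measurement).
- The fixed-margin label assignment makes label-conditional metric
  distributions slightly less separated than the configured group
  distributions whenever the groups overlap.
- Reported cohort-level AUCs from the original 47-patient study are not
  reproducible here: the patient-level data are unavailable, and the
  synthetic cohort only matches published margins and group moments.
- DeLong Wald intervals can degenerate at AUC = 1 (flagged); exact tests
  enumerate and are only intended for small tables.
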