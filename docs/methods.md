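# Methods

This note documents the models implemented in `patreat`, the assumptions
behind the synthetic-data generator, and the numerical and design choices
that were genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Forward model and spectral unmixing

A scene's photoacoustic amplitude at wavelength λ and depth z is modeled
as

    a(λ) = Γ · Φ(λ, z) · [ε_HbO2(λ)·cHbO2 + ε_Hb(λ)·cHb] + noise

with Γ a single proportionality constant folding the Grüneisen parameter
and system gain. Concentrations are therefore *relative* throughout (HbT
is reported in arbitrary units); only StO₂ is an absolute quantity, as Γ
and Φ cancel in the ratio when they are wavelength-independent.

The extinction coefficients at 750/850 nm ship in
`src/patreat/data/hb_extinction.csv`, taken from the Prahl/OMLC
compilation of hemoglobin absorption (518 / 1405.24 and 1058 / 691.32
cm⁻¹ M⁻¹ for HbO₂/Hb). The two wavelengths straddle the ~800 nm
isosbestic point; the resulting 2×2 unmixing matrix has condition number
≈ 3.1, so the per-voxel solve is well posed. The solve uses the analytic
2×2 inverse, vectorized over voxels.

**Noise floor.** Voxels with both amplitudes at or below a floor are
zero-filled and marked invalid. The floor defaults to an absolute
amplitude (0 = "any positive signal counts"); when a background region is
supplied, it is estimated as 3× the pooled background SD. The threshold
defining "signal" is genuinely unspecified in commercial systems, so both
routes are exposed.

**Negative concentrations.** Noise can push a solved concentration
negative. The default policy ("flag") leaves all values untouched and
excludes the voxel from the valid mask — flagged voxels are never
silently altered. The alternative ("range") clips negative concentrations
to zero, which lands StO₂ in [0, 100]. A third policy ("none") keeps raw
values valid wherever HbT > 0; the depth-bias profiler uses it so that
bias beyond the physical range remains visible.

## Fluence model and depth bias

Fluence decays as Φ(λ, z) = Φ₀·e^(−μ_eff(λ)·z), the simplest model
consistent with a tube-phantom experiment; Monte-Carlo transport is out
of scope. Default attenuation pairs (750/850 nm, mm⁻¹):

| medium | μ_eff(750) | μ_eff(850) | rationale |
|---|---|---|---|
| water | 0.0026 | 0.0043 | water absorption only (non-scattering) |
| intralipid_0.5pct | 0.052 | 0.058 | μ_eff = √(3μ_a(μ_a+μ_s′)), intralipid μ_s′ spectrum scaled to 0.5% |
| tissue | 0.11 | 0.12 | generic soft-tissue order of magnitude |

Because μ_eff differs between the wavelengths, the uncorrected solve
acquires a depth-growing StO₂ bias ("spectral coloring"); with these
intralipid values the bias on a 100%-oxygenated tube is negative (Hb is
over-attributed) and increases in magnitude monotonically from 5 to
18 mm. `compensate_fluence` divides each voxel by the model fluence at
its depth; compensating with the generating model removes the bias to
numerical precision. The division is intentionally *not* idempotent and
each application is counted in the metadata. Published intralipid optical
properties vary; the phantom comparison is therefore reproduced
qualitatively (bias shape and removal), not against measured values.

## Scene generation

**Phantom.** A 2-mm polyethylene tube at a configurable depth (5–18 mm)
filled with 2.5 mM hemoglobin at a set true StO₂. Per-frame pulse-energy
jitter is multiplicative Gaussian with relative SD 5/45 (from a 45 ± 5 mJ
pulse energy), identical across wavelengths within a frame — a
system-level fluctuation, not per-voxel noise. Additive amplitude noise
is scaled to the mean in-tube amplitude.

**Tumor.** An ellipsoid ROI whose top sits 8–10 mm below the transducer
(the placement used to keep tumors near the light focus). A fraction
`vascular_fraction` of ROI voxels carries hemoglobin signal — this is
what separates the "average" from the "total" StO₂ biomarkers — and true
StO₂ varies linearly from core to periphery (equal values give a uniform
field). Voxel spacing defaults to 0.1 × 0.1 mm in-plane with 0.15 mm
between frames (the 3D step size of the acquisition protocol).

Axis convention: arrays are (frame, depth, lateral); depth is measured in
mm from the transducer face along the declared axis; indices are 0-based.
The sidecar YAML records wavelengths, spacing, depth axis, seed and a
spec echo.

## Longitudinal cohort generator

The generator emulates a two-group study: implantation on day 0, imaging
three times per week from day 5 (with an extra scan 24 h after the first
dose), daily dosing from day 11 except weekends, euthanasia when the
tumor's longest dimension reaches 20 mm.

* **Growth.** Per-animal Gompertz parameters are drawn from group priors
  (defaults: α ~ N(8, 1.5²) mm³, β ~ N(0.25, 0.025²) day⁻¹,
  κ ~ N(0.030, 0.003²) day⁻¹, truncated positive). These were chosen once
  so that pretreatment (day 10) volumes land in the ~45–85 mm³ range the
  prediction model was developed for and control animals reach the size
  limit around day 45–55. Treated animals' β and κ are multiplied by
  (0.25, 0.125), encoding the observed ~4-fold and ~8-fold reductions in
  the two rate parameters.
* **The reduction applies to the whole trajectory**, not piecewise from
  the treatment start. This makes refitting a single Gompertz per animal
  recover the generating effect exactly, which is what the recovery tests
  need; the cost is that simulated treated tumors are already smaller
  before day 11, a feature real cohorts do not show (their volume curves
  separate only ~10 days into treatment). Conclusions about *pretreatment
  volume* group differences should not be read off this generator.
* **StO₂ dynamics.** Each animal has a baseline StO₂ (62 ± 3%); treated
  animals dip linearly by 15 percentage points over the first 72 h of
  dosing (days 11→14) and, with `weekend_recovery`, return linearly to
  baseline by day 17 — the functional form of the recovery is a modeling
  choice, as only its endpoint ("recovered to pretreatment") is
  constrained. StO₂-total tracks StO₂-average times the vascular
  fraction. Measurement noise SDs default to √4.8 ≈ 2.19 pp (average) and
  √7.40 ≈ 2.72 pp (total), i.e. the repeatability variances the pipeline
  itself is designed to measure; volume noise is 5% multiplicative.
* **Survival.** The event day solves the noiseless trajectory for a
  sphere-equivalent length L = (6V/π)^⅓ reaching 20 mm; animals whose
  trajectory never reaches it inside the 80-day horizon are censored
  there. Under the default effect sizes treated animals rarely event
  within the horizon, so their median survival is typically undefined in
  small simulated cohorts — a stronger divergence than real suboptimal
  dosing produces. No measurements exist after an animal's event day.

What passing tests on this generator demonstrate: correctness of the
estimators and of the chain's plumbing under a known truth. What they do
not demonstrate: robustness to real-tissue fluence heterogeneity,
segmentation error, inter-animal correlation structure, or non-Gompertz
growth.

## Growth model fitting

`GompertzModel.fit` runs bounded nonlinear least squares
(`scipy.optimize.curve_fit`, positivity bounds) on untransformed volumes;
a log-residual option exists because whether volumes or log-volumes were
fit is ambiguous in practice and affects residual weighting.
Initialization: α₀ = first observed volume, β₀ = log-slope of the first
two points, κ₀ = 0.05 day⁻¹; up to 3 log-normally perturbed restarts on
failure; an unconverged fit is returned flagged with NaN parameters,
never silently. Constant-volume series are rejected (the rate is
unidentifiable).

Interval AUCs integrate the *fitted* curve by adaptive quadrature (a
raw-trapezoid alternative on the observations is available through
`numpy` directly; the fitted-curve convention is the package default
since the source of the convention is ambiguous). Two window presets
exist because the pre/during/post delimitations are reported both as
D5–10 / D11–26 / D26–40 ("standard", default) and D5–10 / D10–21 /
D21–40 ("alternate"). Fold-times are found by root bracketing (`brentq`) on the
monotone fitted curve; a target above the plateau α·e^(β/κ) returns
`inf` (censored), not an error. Kaplan–Meier estimation delegates to
lifelines; the median is the first day survival drops to ≤ 0.5 and is
flagged undefined when the curve never reaches it.

## Statistical stage

* **Per-day tests** default to the Student (pooled-variance) unpaired
  t-test, matching the named procedure; Welch is an option.
* **Correlations** are Spearman ρ with average ranks and the
  t-approximation p-value. (Published correlation tables in this area
  sometimes label the coefficient "r²" while showing negative values;
  the quantity here is ρ.)
* **OLS** (statsmodels) with VIF_j = 1/(1 − R²_j) computed by regressing
  each predictor on the others; forward selection greedily maximizes R²
  (adjusted-R² optional) subject to new-coefficient p < 0.05 and all
  VIFs ≤ 3, returning a full trace.
* **Cross-validation.** k-fold (k = 5) partitions a seeded permutation;
  subsampling repeats seeded 80/20 splits (100 repeats). Reported
  coefficients are across-split means; their standard errors are the
  across-split dispersion of that mean (SD/√splits), which collapses to
  0 on noiseless data; R² is the held-out validation R². The model
  p-value shown for CV schemes is the full-sample F-test, since a
  per-split p has no single-value analogue.
* **Responder labeling** thresholds at the 25th percentile
  (linear-interpolation / type-7 quantile, configurable) of the control
  group's fitted β; responder ⇔ β strictly below the threshold.
* **Logistic regression** fits by Newton scoring (IRLS). Complete
  separation — likely in small strongly-dosed cohorts — is detected
  (statsmodels' separation error, or all observations fit to within
  10⁻⁶) and flagged; a lightly ridge-penalized refit then supplies
  finite coefficients and probabilities. ROC analysis is rank-based and
  unaffected by the penalty's monotone shrinkage.
* **Hosmer–Lemeshow** bins by deciles of predicted risk (quantile bins;
  ties merge bins with a warning) and uses g − 2 degrees of freedom,
  the convention calibrated for in-sample fitted probabilities.
* **ROC/AUC.** The empirical tie-aware step curve through (0,0) and
  (1,1); AUC by trapezoid, equal to the normalized Mann–Whitney U.
  AUC standard errors follow Hanley–McNeil by default (the method is
  rarely named alongside published SEs; DeLong is available), with a
  normal-theory 95% CI clipped to [0, 1]. Classification is positive iff
  score ≥ cutoff. The Youden cutoff maximizes TPR − FPR with ties broken
  toward higher specificity, then the higher cutoff; it is always a
  data-derived output, never a constant. Confusion metrics with a zero
  denominator are NaN, not 0.

## Pipeline and reproducibility

`run_pipeline` validates the full configuration before any compute,
hashes it (SHA-256, truncated) into every output's provenance block, and
derives all stage randomness from the single top-level seed, so reruns
are byte-identical. The image-based route re-measures every animal-day
through scene simulation → unmixing → ROI statistics at a coarsened
voxel spacing (0.3 × 0.2 × 0.2 mm by default), which keeps the
16-animal demo under a minute on one CPU while leaving volumes accurate
to a voxel shell. The acceptance script's problem sizes (200 cohorts ×
29 animals) match the regression stage's design regime.

## Known limitations

* Two wavelengths only; ≥3-wavelength or learned unmixing, Monte-Carlo
  fluence modeling, and acoustic reconstruction are out of scope.
* The generator's trajectory-wide treatment effect exaggerates
  pretreatment group separation in volume (see above).
* Commercial oximetry modes are proprietary; agreement is asserted with
  the stated two-wavelength model, not with any vendor implementation.
* Tumor masks are inputs; no segmentation is provided.
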