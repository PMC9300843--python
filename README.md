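# patreat

Monitoring and predicting tumor treatment response from 3D
ultrasound-guided photoacoustic imaging.

`patreat` is a Python package for preclinical oncology groups who use
dual-wavelength photoacoustic (optoacoustic) imaging to follow
subcutaneous tumors through a course of antiangiogenic or tyrosine-kinase
inhibitor therapy — a setting where the dose is often suboptimal, volume
changes lag, and early oxygenation changes carry the predictive signal.
It implements the full analysis chain from raw amplitude volumes to a
treatment-response classifier, plus a synthetic-data module that generates
every pipeline input with known ground truth, so the whole chain is
testable without animal data.

## What it computes

**Spectral unmixing.** Per voxel, the photoacoustic amplitudes at 750 and
850 nm are an absorption-weighted mix of oxy- and deoxyhemoglobin:

    a(λᵢ) = ε_HbO2(λᵢ)·cHbO2 + ε_Hb(λᵢ)·cHb ,  i = 1, 2

Inverting this 2×2 system gives relative concentrations, from which
StO₂ = 100·cHbO2/(cHbO2 + cHb) and HbT = cHbO2 + cHb. A Beer–Lambert
fluence model Φ(λ, z) = Φ₀·e^(−μ_eff(λ)·z) quantifies (and can correct)
the depth-dependent "spectral coloring" bias, reproducing the behavior of
blood-tube phantoms at 5–18 mm depth in water and 0.5% intralipid.

**ROI biomarkers.** Over a tumor mask: *StO₂ average* (mean over
signal-bearing voxels), *StO₂ total* (mean over all ROI voxels, zeros
included — never larger than the average), HbT analogues, voxel-count
volume, the caliper volume L·W·H·π/6, and session-to-session
repeatability variance.

**Growth kinetics.** Each animal's volume trajectory is fit with the
Gompertz law

    V(t) = α · exp[(β/κ)(1 − e^(−κt))]

(α initial volume, β initial specific growth rate, κ its decay rate),
from which interval AUCs (pretreatment / on-treatment / posttreatment),
2×/5×/10× fold-increase times, and Kaplan–Meier survival of size-limit
events are derived.

**Response prediction.** Per-day unpaired t-tests, a Spearman correlation
matrix, and the multivariate model

    β = b₀ + b₁·(pretreatment volume) + b₂·ΔStO₂(D7–D10) + b₃·ΔStO₂(D10–D14)

fit by OLS with forward selection (VIF-gated), 5-fold and repeated
80/20-subsampling cross-validation; responders (growth rate below the
25th percentile of the untreated group) are then classified by multiple
logistic regression, evaluated with Hosmer–Lemeshow, ROC/AUC
(Hanley–McNeil or DeLong standard errors), the Youden-optimal cutoff, and
confusion metrics.

## Worked example

```python
from patreat import CohortSpec, simulate_growth_cohort, fit_cohort, km_estimate
from patreat.pipeline import build_feature_table, PREDICTORS
from patreat.predict import GrowthRateModel, ResponderModel

cohort = simulate_growth_cohort(CohortSpec(), seed=42)   # 8 control + 8 treated
fits = fit_cohort(cohort.table)                          # per-animal Gompertz
print(fits.groupby("group")[["beta", "kappa"]].mean().round(4))
#          beta   kappa
# group
# 0      0.2900  0.0358
# 1      0.0627  0.0026

feats = build_feature_table(cohort.table, fits)
print(ResponderModel(feats, PREDICTORS).fit().summary())
# Responder prediction
# ======================================================
# responder threshold (growth rate): 0.2149 /day
# responders: 10 / 16
# separation flagged: False
# ROC AUC = 0.950 (SE 0.055, 95% CI 0.842-1.000, p = 4.09e-16)
# Youden cutoff = 0.677
# sensitivity 90.0%  specificity 100.0%  PPV 100.0%  NPV 85.7%
# Hosmer-Lemeshow chi2 = 4.36 (df 6, p = 0.628)
# ======================================================
```

The treated group's refitted growth rate β is ~4-fold lower than the
control group's (0.063 vs 0.290 /day) — the generating effect — and the
three-predictor responder model separates the groups with AUC 0.95.

The same chain runs from the shell, including the image-based route in
which every animal-day is simulated as a 3D scene, spectrally unmixed and
reduced to ROI biomarkers before any statistics happen:

```sh
patreat run --out demo_run --seed 1      # simulate → unmix → metrics → growth → predict
patreat report --report demo_run/report.json
```

Subcommands `simulate`, `unmix`, `metrics`, `growth` and `predict` expose
the individual stages; see `patreat --help`.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator's
assumptions and limitations, numerical choices and tie-breaks.
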