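# Methods

`nigm` is a simulation-backed reimplementation of the analysis pipeline behind a
Raman-based non-invasive glucose monitor (NIGM): a two-day in-clinic study with
meal-induced glucose excursions, a six-step spectral preprocessing chain, a
shallow 1-D CNN calibrated by population pretraining plus per-subject
fine-tuning, and the standard clinical accuracy readout (MARD, RMSE, Consensus
Error Grid, interstitial delay, covariate correlations). No clinical data are
distributed; every input is produced by the seeded study simulator, and the
latent truth it retains is what the tests score against.

## Study simulator

**Schedule.** Day 1: 10 calibration sessions at 20-min spacing (08:00–11:00),
then 14 validation sessions at 15-min spacing; day 2: 26 validation sessions at
15-min spacing. Every session takes 4 hand placements and 2 capillary (BGSM)
samples; a venous sample accompanies every calibration session and every second
day-1 validation session. A 50-subject fault-free study therefore schedules
exactly 2000 validation points.

**Glucose kinetics.** Capillary glucose = subject baseline (loosely tied to the
subject's HbA1c) + one meal response per served meal + slow AR(1) drift
(sd 0.3 mmol/L, 60-min correlation time), clipped at 3.9 mmol/L because the
study design produced no hypoglycemia. A meal response is a difference of two
exponentials (rise 15 min, decay 90 min) scaled linearly by grams of
carbohydrate (0.05 mmol/L peak per gram; breakfast 70 g, lunch 80 g).
Interstitial glucose is a first-order lag of the capillary trace,
`G_isf' = (G_cap − G_isf)/τ`, with per-subject τ drawn from N(10, 9²) min
truncated at 1 min. Venous glucose is the capillary trace delayed 5 min with
post-prandial excursions attenuated by 10% — the direction reported for
venous-capillary differences; magnitudes are this package's choice.

**References.** Capillary: two independent draws at 3% CV (typical SMBG
performance); venous: one draw at 1.5% CV (laboratory analyzer). Only the
ordering (venous more accurate) is documented for the real instruments; the
values are chosen from typical published device performance.

**Spectra.** Each placement yields ten 1024-pixel frames (a 50-s acquisition
cut into 5-s frames — the real cadence is unpublished; ten frames make temporal
despiking and √n averaging meaningful). A frame is rendered through a
per-device quadratic pixel→wavenumber map (covering ≥ 300–1615 cm⁻¹ by
construction, jittered ends) as:

* fluorescence background: a broad smooth curve, ~1000 counts for phototype
  I–II skin, scaled by a Fitzpatrick-phototype multiplier (0.8 → 2.8 for
  I → VI, monotone: darker skin fluoresces more) and a per-subject lognormal
  jitter (log-sd 0.15);
* glucose signature: Gaussian bands at 911, 1060, 1125 cm⁻¹ (literature
  glucose Raman bands), amplitude 6 counts per mmol/L of *interstitial*
  glucose — roughly 0.5–2% of the background. This coupling was fixed at
  design time so that session-level prediction noise lands in the regime the
  published accuracy implies (~0.5 mmol/L), compensating for a pretraining
  corpus ~14× smaller than the clinical one;
* confounder bands: skin protein/lipid features. Strong structural bands
  (phenylalanine 1003, CH₂ 1445 cm⁻¹) are nearly stable across subjects
  (log-sd 0.10–0.15) and act as internal intensity anchors; weaker features at
  898, 1065, 1128 cm⁻¹ deliberately overlap the glucose bands and vary
  strongly between subjects (log-sd 0.30). The overlap is what makes
  per-subject calibration *necessary*: without it a population model reads a
  subject's collagen/lipid levels as a glucose offset. Band amplitudes also
  drift slowly within a day (2.5% per placement);
* shot noise (`√intensity` Gaussian) and Poisson(1.5)/frame cosmic-ray spikes,
  1–2 pixels wide, every spiked pixel ≥ 8× the local noise scale. Spike
  locations are kept as truth masks.

All randomness descends from one `SeedSequence` with named per-subject
substreams; identical seed + config reproduce the bundle exactly.

**What the simulator does not model:** radiative transfer and skin optics,
detector electronics, wavelength drift within a device, circadian physiology,
inter-day sensor aging. Passing tests demonstrate that the *analysis chain* is
correct and that the calibration scheme behaves as designed under the stated
statistical structure — not that the device itself performs as published.

## Preprocessing (six steps)

1. raw frames (1024 pixels) →
2. **despike**: per pixel across the frame series, values above
   median + 6·MAD (MAD in σ-consistent units, pooled over a 15-pixel window to
   stabilize the noise estimate) are replaced by the temporal median; below 4
   frames a rolling Hampel test along the pixel axis is used. One-sided,
   because cosmic spikes are positive. A zero-MAD (constant) series falls back
   to an absolute floor and passes through unchanged.
3. **align**: linear interpolation from the device wavenumber grid onto 700
   equidistant points spanning 300–1615 cm⁻¹ inclusive (~1.9 cm⁻¹ spacing;
   linear suffices at ~10 cm⁻¹ device resolution).
4. **average** the placement's frames (SNR ∝ √n).
5. **normalize** to unit ℓ2 norm (ℓ1/area available as a switch); the source
   chain says only "normalization", ℓ2 is the standard chemometric choice.
6. **center** by subtracting a fixed population mean spectrum fitted once on
   the pretraining corpus — population-level rather than per-spectrum, so
   band structure is retained while spectra vary around zero.

No baseline subtraction and no spectral-outlier gate are applied, matching the
source chain.

## Calibration network

Exactly four layers on the 700-point input: 1-D convolution (8 filters,
kernel 25, stride 5, ReLU) → flatten (136×8) → dense (96, ReLU) → one linear
output neuron, clamped below at 0.5 mmol/L. Trainable parameters:
208 + 104 544 + 97 = **104 849** (~105k); `build_model` guards the default
architecture to the [95k, 115k] budget. Forward, backward and Adam are
implemented directly in NumPy — at this size a framework adds nothing, and the
arithmetic is unit-tested against finite differences.

**Pretraining.** MSE in mmol/L, Adam (lr 1e-3, batch 64, ≤150 epochs), inputs
standardized to unit RMS by a scale stored in the model, weight decay 1e-2,
early stopping (patience 50, best weights restored) on a subject-grouped
hold-out — the stopping criterion must measure generalization to unseen
subjects, which is how the model is deployed. Small simulated corpora are easy
to memorize via subject "fingerprints"; the weight decay exists to suppress
that shortcut. After training, the model records its **population gain** λ̂:
the mean per-subject slope of prediction vs reference on the held-out
subjects. An MSE-optimal predictor of noisy spectra shrinks within-subject
excursions (λ̂ ≈ 0.65–0.75 at default settings), and the fine-tuning stage
needs to know by how much.

**Fine-tuning (default, `proximal`).** Ten morning calibration sessions span
under ~1.5 mmol/L of glucose, which identifies a subject's *offset* but not a
new regression surface; naive gradient fine-tuning on such data collapses the
network toward a constant, and a plain offset correction mis-transfers because
of the shrinkage above (the bias measured at the low morning level differs
from the bias during excursions by (λ̂−1)·ΔG). The default fine-tune is
therefore a closed-form output-layer recalibration: (i) anchor the prediction
at the calibration references and divide out the population shrinkage
(slope 1/λ̂ — the unbiased choice; a `gain_shrink` knob can soften it toward
an offset-only correction); (ii) a ridge fit of the remaining
calibration residuals on the dense-layer features, penalized toward the
pretrained output weights with the offset free, absorbs subject-specific
spectral interference. The convolutional and dense layers stay frozen; the
update is deterministic. The gradient-descent variant (Adam on dense+output,
early stopping on training loss) is kept as `finetune_mode="sgd"` for
comparison. Calibration references use the venous value when drawn (every
calibration session has one), else the BGSM duplicate mean.

## Evaluation

* Sessions whose BGSM duplicates differ by **strictly more than 1 mmol/L** are
  dropped (a 1.0 mmol/L difference is kept); sessions missing a duplicate are
  excluded and counted separately, and the report prints the full accounting
  (scheduled = kept + dropped + missing).
* Reference = duplicate mean (capillary) or the venous value; NIGM value =
  mean of the 4 placement predictions.
* MARD = 100·mean(|pred−ref|/ref); RMSE in mmol/L; 95% CIs by percentile
  bootstrap over *subjects* (2000 resamples, seeded), which respects
  within-subject correlation; the median per-subject MARD gets its own
  bootstrap interval.
* Consensus (Parkes) error grid: both published breakpoint sets are encoded
  (type 1 and type 2); default **type 2** because the simulated cohort is
  type 2 diabetes. mmol/L→mg/dL at 18.016. Boundaries are polylines extended
  past their last vertex with the final slope; boundary points take the
  lower-risk zone. Tests verify zone assignment against an independently
  coded shapely point-in-polygon oracle.
* Interstitial delay: the reference series is shifted over a 0–30 min grid
  (1-min steps, linear interpolation onto the NIGM timestamps) and the lag
  maximizing Pearson correlation is reported, per day, averaged. Note a
  first-order lag is not a pure delay: the shift estimator is unbiased to the
  minute for τ ≲ 10 min but underestimates long time constants (τ = 20 min
  recovers ≈ 16 min on noise-free traces) because the fast meal-rise spectral
  content carries less than τ of group delay. This is a property of the
  estimator, shared with its clinical use.
* Covariates (age, sex 0/1, BMI, HbA1c, phototype ordinal 1–6, stratum-corneum
  thickness) correlate against per-subject MARD by Pearson r with two-sided
  t-distribution p-values (n−2 df); zero-variance covariates are flagged.
* Calibration sweep: fine-tune on the chronologically first n = 1…10
  calibration sessions, evaluate all validation sessions.
* Reference comparison: on day-1 sessions holding both reference types,
  improvement = 100·(metric_cap − metric_ven)/metric_cap.

## Problem sizes used in tests

Unit tests run on 1–2 simulated subjects. The end-to-end acceptance checks
pretrain on 40 simulated subjects (50 sessions × 4 placements = 8000 spectra)
and evaluate 10 replicate study cohorts of 8 subjects (40 validation
sessions each); the venous-vs-capillary comparison resamples references 20
times from the latent truth of one cohort. These sizes are the package's
working scale for a desk-top reproduction; the generating process itself is
identical at any cohort size.

## Known limitations

* The NumPy trainer is single-threaded BLAS-bound; it is sized for thousands,
  not hundreds of thousands, of spectra.
* The proximal fine-tune corrects offset and population-level slope; a
  subject whose individual response slope deviates strongly from λ̂ retains a
  residual excursion-proportional error, which morning-only calibration
  cannot identify even in principle.
* Bootstrap CIs are percentile intervals; no BCa correction.
* The simulator's count scale is arbitrary (no exposure time or duty cycle is
  modelled), so absolute intensities mean nothing — only ratios do.
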