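# Methods

## Scope and model

The package quantifies glucose in biofluids from mid-infrared absorbance
spectra (1200–925 cm⁻¹, the glucose fingerprint region) by partial
least-squares calibration, and ships a forward simulator so the complete
analysis — preprocessing, model selection, validation — can be exercised
and tested without access to animal samples.

Absorbance is decadic, A = −log₁₀(I/I₀), from a sample intensity I and a
water-reference intensity I₀. The spectral grid defaults to 1200 → 925 cm⁻¹
in 1 cm⁻¹ steps (276 points, descending to match the laser tuning sweep);
the spacing is an assumption of the simulator, recorded here because the
acquisition point density is not otherwise constrained. All operations are
orientation-agnostic.

## Forward simulation

**Analyte bands.** Each analyte is a superposition of Gaussian or Lorentzian
bands parameterised by centre, FWHM and peak absorptivity in
AU/(mg/dL)/mm. Defaults: glucose at 1035 cm⁻¹ (the fingerprint band the
calibration relies on) plus weaker bands at 1080 and 1110 cm⁻¹; an
albumin-like protein as one broad band at 1080 cm⁻¹; lactate as a minor
band at 1125 cm⁻¹. These shapes reproduce the qualitative appearance of
biofluid mid-IR spectra; they are tunable generator defaults, not
literature constants.

**Instruments.** Transmission: fixed 200 μm pathlength (the optimal fibre
gap for aqueous mid-IR work). ATR: 11 reflections on the internal
reflection element, each contributing an effective pathlength
d_e(ν) = s·(ν_ref/ν) with s = 3 μm at ν_ref = 1035 cm⁻¹ — the evanescent
field penetrates deeper at longer wavelengths, and absorbance grows
approximately linearly with the reflection count. The ATR optical path also
carries a multiplicative sinusoidal fringe (etalon-like interference),
relative amplitude 1 %, period drawn per sample from 6–7.5 cm⁻¹ with random
phase. That period range puts the fringe at raw-DFT bins ≈ 37–46 of the
276-point grid — above the Fourier filter's transition band
(28 × 1.3 ≈ 36.4) — while analyte bands (FWHM ≥ 16 cm⁻¹) stay below bin
≈ 18, so fringe and signal are separable by design, as they must be for the
filter to work at all.

**Measurement noise.** I₀ is a smooth positive source envelope with
per-point multiplicative Gaussian noise; I additionally carries the fringe
term and 10^(−A) attenuation. Nonpositive simulated intensities raise an
error rather than being clipped — clipping would bias the log transform.
Identical seeds give bit-identical draws, and the draw order
(phase, period, reference noise, sample noise) is fixed, so scaling the
noise SD under a fixed seed rescales the same realisation; the noise
monotonicity tests rely on this.

**Cohorts.** A cohort is n individuals × m samples. Per-individual effects
— matrix concentration factors (CV 6 %) and a smooth spectral baseline
(offset/slope/curvature, SDs 5·10⁻⁵/5·10⁻⁵/2.5·10⁻⁵ AU at the 200 μm
reference path, scaled with effective pathlength) — are a pure
deterministic function of the individual ID string; generated IDs embed the
cohort seed so different seeds give different individuals. Within-individual
matrix jitter has CV 3 %. A configurable fraction of samples is spiked with
10 000 mg/dL glucose stock to a uniform target; the added volume
v = V(c_t−c₀)/(c_s−c_t) must stay below 5 % of the sample volume, and
matrix concentrations are diluted by V/(V+v), mirroring wet-lab spiking
with dilution-corrected reference values. Reference glucose is exact ground
truth by default (an optional Gaussian reference error is a config switch).

**Study conditions.** The peritoneal scenario uses 5 individuals × 16
samples (80 total; 79 after the grouped split drops one validation sample,
since 79 is not divisible across 5 individuals), base glucose uniform in
33–140 mg/dL, half the samples spiked towards 150–426 mg/dL. The plasma
scenario uses 2 individuals, 21 samples (2 × 11 capped at 21), base
65–105 mg/dL spiked towards 110–346 mg/dL, with total protein 2.2× the
peritoneal level — plasma spectra therefore show visibly higher total
absorbance.

**Noise calibration.** The detector noise SDs (1.5·10⁻⁴ transmission,
3.5·10⁻⁵ ATR, relative intensity units) together with the variability
figures above are a frozen calibration: they were chosen once, by a sweep
over candidate values, so that the three benchmark scenarios land near the
reference prediction errors for this kind of measurement (transmission
grouped holdout ≈ 7 %, ATR ≈ 9 %, plasma LOOCV ≈ 5 % MAPE), and are not
revisited. They are a calibration of the simulator, not a measurement of
any instrument.

What the simulator deliberately omits: dispersion (Kramers–Kronig) and
radiative-transfer effects, temperature dependence, the unexplained
1045 cm⁻¹ feature of non-centrifuged fluid, and physiological correlation
between glucose and electrolyte/matrix levels. Passing benchmarks therefore
show that the pipeline recovers concentrations under realistic noise,
inter-individual background variation and fringe interference — not that it
would meet the same error on real spectra, whose matrix variability is
unknown.

## Preprocessing

Pipeline order is fixed: filter → derivative → baseline → normalisation →
mean-centering. The order is a convention of this package (common
chemometrics practice) and is embedded in every serialised report.

- **Savitzky–Golay**: convolution weights derived internally by solving the
  local least-squares polynomial system (the (5, 2) weights reproduce the
  classical (−3, 12, 17, 12, −3)/35). Edges use shrink-window asymmetric
  fits of the same polynomial order, which keeps polynomial reproduction
  exact everywhere and is deterministic.
- **Fourier filter**: the spectrum is evenly (symmetrically) extended to
  suppress wrap-around edge artefacts; bins up to the cutoff pass
  unchanged; a 4-term Blackman–Harris taper (coefficients 0.35875, 0.48829,
  0.14128, 0.01168) descends over a transition band of
  cutoff × (multiplier − 1) bins; higher bins are removed. Cutoffs count
  one-sided frequency bins of the raw (unextended) signal — the counting
  convention is ambiguous in general usage and is fixed and documented
  here. Defaults: cutoff 28, multiplier 1.3.
- **Derivatives** are SG derivatives (width 9, polynomial order
  max(2, order)), scaled by the signed grid spacing — the standard
  spectroscopy choice over bare finite differences.
- **Baseline correction** subtracts the line through the first and last
  point; **normalisation** scales to unit Euclidean norm.

Row-wise operators are training-independent; only column means (and the
response mean) are learned, always on training rows only. The default model
grid is the Cartesian product of 3 filters × 3 derivative settings ×
2 baselines × 2 normalisations = 36 pipelines.

## PLS

NIPALS-PLS1, written from scratch. For a single response no inner iteration
is needed: w ∝ Xᵀy in closed form each round. Component extraction stops
early with a warning when the score energy tᵀt falls below 10⁻¹² of the
initial ‖X‖²_F, so requesting more components than the residual rank
supports degrades gracefully instead of amplifying noise. Each weight
vector's largest-magnitude element is forced positive for cross-platform
reproducibility. The regression vector is b = W(PᵀW)⁻¹q; because PLS1
components are nested, one fit at the maximum LV count serves every smaller
count during grid search. At full rank PLS coincides with least squares,
which the tests use as an oracle (scikit-learn's PLSRegression serves as an
independent cross-check, never as the implementation).

## Validation designs and metrics

- **Random-subset CV** (default 10 splits, 20 iterations): per iteration,
  shuffle with an iteration-derived seed, partition into near-equal folds
  (remainders to the first folds), hold out each fold once, pool the
  held-out predictions into a per-iteration MAPE. The reported CV MAPE is
  the **mean of per-iteration pooled MAPEs**; the fully pooled variant is
  also computed and labelled, since the aggregation convention is a genuine
  free choice.
- **LOOCV**: n deterministic single-sample folds (21 fits for the plasma
  set).
- **Grouped holdout**: one fit on all samples of the training individuals,
  evaluated on disjoint validation individuals; overlapping groups are an
  error. Preprocessing statistics never see validation rows anywhere
  (enforced by mutation tests).

Metrics: MAPE (%), RMSE, SEP = bias-corrected residual SD
(√(Σ(e−ē)²/(n−1))), and R². MAPE requires strictly positive references.

**Grid search** scores every (pipeline, LV) candidate on identical fold
partitions (one shared seed) and breaks ties by fewer LVs, then fewer
active preprocessing steps, then enumeration order — a parsimony rule,
needed because CV alone reports a single minimal value.

## Study runner and reproducibility

`run_study` executes four scenarios (peritoneal/plasma × transmission/ATR):
grid search on the training portion (random-subset CV for the peritoneal
48/31 design, LOOCV for plasma), evaluation per the scenario's scheme, and
a report bundle (JSON metrics in mg/dL and mmol/L, per-sample predictions
CSV, the full grid table, and a manifest with the config hash and all
derived seeds). Per-scenario seeds are a stable hash of (master seed,
scenario name), so adding scenarios never shifts existing results. A
scenario failure is logged and recorded without aborting the others.
Reruns with the same config are byte-identical.

The benchmark scenarios reported by `scripts/acceptance.py` use the frozen
reference configurations — SG(9, 1) with 5 LVs (transmission), Fourier
(28, 1.3) with 5 LVs (ATR), SG(9, 1) with 6 LVs (plasma LOOCV) — averaged
over ten cohort seeds derived from the script's `--seed`. Problem sizes
(80-sample cohorts, 36-pipeline grid, LV 3–12) keep a full study in the
tens of seconds on one CPU; the package's tests reduce CV iteration counts
where the property under test does not depend on them.

## Known limitations

- Band absorptivities and variability magnitudes are plausible defaults,
  not fitted to measured spectra; absolute absorbance scales should not be
  compared against real instruments.
- The fringe model is a single sinusoid per sample; real etalon structure
  can be multi-component and drift within a sweep.
- The spiking model extends the glucose range without the correlated
  electrolyte/matrix shifts real physiology would produce, so
  between-individual generalisation is likely easier here than in vivo.
- MAPE weights errors by 1/y, so low-concentration samples dominate; the
  RMSE/SEP/R² suite is reported alongside for that reason.
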