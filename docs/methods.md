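# Methods

This note documents the model, estimators, numerical choices and known
limitations of `atrquant`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Measurement model

A film deposited on the ATR crystal yields an absorbance spectrum that we
model, for a closed binary mixture of piperacillin (PIP) and tazobactam
(TAZ), as

    M(ν) = g · [C_PIP·R_PIP(ν) + C_TAZ·R_TAZ(ν)]/100 + d(ν) + ε(ν)

where R_PIP, R_TAZ are pure-component response spectra per 100 % w/w, g is a
film-deposition scale (non-uniform analyte deposition changes the effective
amount probed by the evanescent wave multiplicatively), d is a slowly varying
instrumental baseline approximated as a straight line, and ε is measurement
noise. The analysis statistic

    y = I(873)/I(890)

uses baseline-anchored peak heights: the one baseline is the straight line
through the spectrum's (linearly interpolated) values at 862 and 905 cm⁻¹,
and each height is the maximum baseline-corrected absorbance within
±4 cm⁻¹ (the nominal instrument resolution) of the peak position. Two
exact cancellations follow and are enforced as property tests:

* the anchored baseline absorbs **any** affine component d(ν) = d₀ + d₁ν;
* the ratio is invariant under the multiplicative scale g.

With closure C_PIP + C_TAZ = 100 and a TAZ response at 890 cm⁻¹ that is
negligible relative to the strong PIP band there, the mixture ratio is an
affine function of x = 100/C_PIP:

    y = (P873 − T873) + T873·x  ≡  a + b·x,

where P873, T873 are the component responses at 873 cm⁻¹ normalized to the
PIP response at 890 cm⁻¹. This is the linearization that makes a single
unweighted least-squares line quantify both APIs at once.

## Estimators

**Calibration.** Simple linear regression of y on x, either on per-standard
mean ratios (`on_means`, appropriate when only summary ratios are available)
or on every replicate film (`on_replicates`, the default; for a balanced
design both give the same line). Standard errors use the textbook forms
se_b = s/√Sxx, se_a = s·√(1/n + x̄²/Sxx) with s² = SSres/(n−2). A two-point
design yields an exact line with NaN standard errors and a warning; zero
spread in x is an error.

**Inverse prediction.** C_PIP = 100·b/(ȳ − a), C_TAZ = 100 − C_PIP (closure
is exact by construction). Ratios at or below the intercept have no positive
solution and raise; recovered C_PIP > 100 (ratio below the pure-PIP point)
and TAZ contents outside the calibrated 5–50 % w/w range are returned but
flagged.

**Uncertainty.** Default is the replicate-only delta method,
sd(C_PIP) = 100·b/(ȳ−a)² · se(ȳ) with se(ȳ) the standard error of the mean
replicate ratio; sd(C_TAZ) equals it by closure. An opt-in `extended` mode
adds the first-order contributions of se_a and se_b assuming independence
(dC/db = 100/(ȳ−a), dC/da = 100·b/(ȳ−a)²). The replicate-only default was
chosen because the replicate scatter dominates for typical 3-film
measurements and requires no assumption about parameter covariances.

**Detection limits.** From n ≥ 2 blank (pure-PIP film) ratio measurements,
the decision ratio y_D = ȳ_b + k·s_b (k = 3 default) is inverted through the
calibration line; LOD_TAZ = 100 − C_PIP(y_D). LOQ defaults to 3·LOD
("factor" mode) — the convention consistent with a published LOD/LOQ pair of
1.618/4.854 % w/w whose quotient is exactly 3 — with an ICH-style
k_Q·s_b "ratio" mode (k_Q = 10) available.

## Synthetic data generator

Pure-component spectra are sums of unit-height pseudo-Voigt bands
η·L + (1−η)·G (η = 0.7, FWHM = 6 cm⁻¹ by default) placed at the APIs'
characteristic mid-IR positions (PIP: 728–1764 cm⁻¹ inventory; TAZ: its
sulfone/triazole bands plus the enhancement markers at 873, 945, 1023,
1081 cm⁻¹). Only the four anchor amplitudes are calibrated: requiring the
noiseless pipeline to reproduce a target line y = b·x + a gives
T873 = b, P873 = a + b, with P890 = 1 as normalization and T890 = 0. All
other amplitudes are fixed plausible constants — the compounds' relative
band intensities are not tabulated anywhere we rely on — so synthetic
spectra are *structurally* faithful (band positions, overlap topology,
noise structure), not spectroscopically faithful.

Replicates draw g ~ lognormal(0, σ_g = 0.2), a drift line with slope
≤ 2×10⁻⁵ a.u./cm⁻¹ and offset ≤ 0.01 a.u., and i.i.d. Gaussian noise, all
seeded deterministically per (seed, composition, replicate).

Numerical choices worth recording:

* **Grid.** 600–4000 cm⁻¹ at 1 cm⁻¹ spacing. A 2 cm⁻¹ grid anchored at an
  even wavenumber cannot contain both 873 (odd) and 890 (even) cm⁻¹; the
  off-grid apex would be sampled ≈9 % low and bias the ratio, so the default
  grid places both quantification bands on-grid.
* **Additive noise default (0.012 a.u.).** Set once by a bisection loop
  (`calibrate_additive_noise_sd`, seed 123, shipped for reproducibility but
  not called at runtime) so that the mean 3-replicate ratio RSD at the 10:90
  TAZ:PIP composition is ≈3 %, the middle of the 2–4 % range typical of
  replicate film depositions.
* **Band-overlap tolerance.** With 6 cm⁻¹ FWHM bands 17 cm⁻¹ apart and
  anchors 11/15 cm⁻¹ from the peaks, Lorentzian tails perturb the noiseless
  pipeline ratio by up to ≈0.04 at 50:50; noiseless reproduction of the
  target line is therefore asserted to 0.05 absolute, and the noiseless
  pure-PIP ratio to 0.22 ± 0.02. Because calibration and unknowns pass
  through the same pipeline, this bias largely cancels in recovered
  compositions (noiseless inversion round-trips to ~0.01 % w/w).

What passing synthetic tests shows — and what it does not: they validate the
statistics (linearity in x, cancellation properties, estimator correctness,
uncertainty scale) under the stated noise model. They cannot validate
instrument physics the generator omits: wavenumber-dependent ATR penetration
depth, crystal contact quality, atmospheric CO₂/H₂O bands, polymorphic
shifts, or non-affine baselines.

## Degenerate inputs and tie-breaks

* Descending-wavenumber exports are normalized to ascending; duplicate
  wavenumbers are rejected with the offending row.
* Apex search uses the grid-point maximum of the corrected signal in a
  closed ±4 cm⁻¹ window (ties resolve to the lowest wavenumber via argmax);
  the apex actually used is reported for audit. A `fixed` mode reading the
  height exactly at the nominal wavenumber is available; `apex` is default
  because it is robust to ±1–2 cm⁻¹ band shifts.
* Corrected heights ≤ 0 are reported with a warning (`detected=False`)
  rather than clipped; a ratio with denominator ≤ 10⁻¹² raises, since no
  PIP reference peak means the film is not a PIP-containing sample.
* Qualitative matching accepts local maxima with prominence ≥ 3× a noise
  scale taken as the median absolute successive difference — a robust
  estimate that ignores the (sparse) bands.
* The JCAMP-DX reader supports only uncompressed `XYDATA=(X++(Y..Y))`
  records with AFFN ordinates and rejects anything else loudly.

## Problem sizes

Default study design mirrors a realistic bench protocol: six standards
(TAZ 50, 45, 25, 15, 10, 5 % w/w) × 3 replicate films, 20 blank films, and
3-replicate unknowns on a 3401-point grid. The acceptance script runs one
such simulation per invocation; the stochastic end-to-end test repeats it
for three seeds.

## Known limitations

* Univariate only: one ratio, one line. No PLS/PCR, no >2-component
  mixtures, no prediction intervals beyond first-order propagation.
* The blank statistics behind a given published LOD are generally not
  recoverable from the LOD alone; the factor-mode LOQ is a convention, not a
  derivation.
* Whether a published line was fitted on means or on replicates matters in
  the third decimal of the coefficients; both modes are exposed, and the
  printed-table reproduction uses `on_means` because only means are printed.
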