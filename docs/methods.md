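# Methods

## Signal model and processing chain

The device records three spectra on a common wavelength grid: the nail-bed
sample, a dark acquisition (source off), and a reference from a standard
diffuse scatterer. The processed quantity is the decadic absorbance
`A(λ) = −log₁₀((S−D)/(R−D))`, computed pointwise and cropped to the
450–650 nm working band. The dark/reference correction cancels ambient
light and the scatterer's spectral shape; the result is treated as an
absorbance-like quantity, not a rigorous Beer–Lambert absorbance, since
diffuse reflectance mixes absorption with path-length effects.

Spectra may be smoothed with a centered boxcar (running average) of width
`w`, meaning a `(2w+1)`-point window. Edge points use symmetrically
truncated windows; padding would fabricate data at the band edges. The
device's operating width is 2. Smoothing is a noise-control measure: on a
smooth Gaussian peak it introduces a curvature bias of order
`w(w+1)/6 · h² · |A''| ≈ 5·10⁻⁴` absorbance at the 0.47 nm sampling
interval, which is negligible against detector noise but not against
machine precision. Exact-roundtrip checks on noiseless synthetic data are
therefore run with width 0, and noisy data with the operating width 2.

### Amplitude gate

A geometry gate requires the absorbance at 620 nm — obtained by linear
interpolation between the flanking grid points — to lie in the inclusive
interval [0.5, 0.6]. The window encodes correct spot size and
probe-to-nail distance. The published description of this rule uses an
inconsistent inequality chain; the prose ("within 0.5 and 0.6") fixes the
intended reading as an interval, which is what is implemented. By default
a gate failure is recorded but does not abort the pipeline; in strict mode
(`gate.strict = true`) it rejects the measurement with re-acquisition
guidance, mirroring the device's behaviour.

## Five-Gaussian deconvolution

The absorbance spectrum is modelled as a shared offset plus five Gaussian
components at fixed centers: 462.92 nm (bilirubin), 539.34 and 577.2 nm
(oxyhemoglobin Q bands), 568.09 nm (deoxyhemoglobin) and 620 nm (a
baseline/scattering correction term that participates in the fit but never
in any index). Each component is `A·exp(−0.5((λ−x_c)/w)²)`; `w` is the
Gaussian σ parameter exactly as it appears in the model equation (some
descriptions call it a FWHM, but the functional form makes it σ; the FWHM
`2√(2 ln 2)·w` is reported as a derived field).

The 11 free parameters (5 amplitudes, 5 widths, 1 offset) are estimated by
bounded nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective) minimizing the mean squared residual. Choices:

* **Bounds**: `A ∈ [0, 10]`, `w ∈ [1, 60]` nm, offset in `[−10, 10]`.
  Amplitudes are physically non-negative; the width cap prevents one
  component degenerating into a baseline.
* **Initial guess**: offset = min(absorbance); `Aᵢ` = absorbance at the
  center minus the offset (floored at 0); `wᵢ` = 10 nm. With centers
  fixed, the problem is mildly nonlinear and this start converges on all
  synthetic fixtures; the start is deterministic, so identical inputs give
  bit-identical results.
* **Tolerances**: `xtol = ftol = gtol = 1e−14`, tight enough that
  noiseless synthetic spectra are recovered to better than 1e−6 relative
  in all 11 parameters.
* Parameters pinned at a bound are reported as warning flags rather than
  errors; non-convergence raises an error carrying the best iterate.

### Residual-based acceptance

A fit is accepted when the fraction of residuals with `|r| ≤ 0.02`
absorbance (inclusive) meets the configured partition: 0.98 by default,
with 0.90 and 0.95 selectable. The published tolerance is written both as
"±0.02%" and as "±0.02"; it is implemented as ±0.02 in absolute absorbance
units, since residuals are assessed on the absorbance scale and a
relative 0.02% band around a ~0.5 signal would reject essentially every
real spectrum. Acceptance is monotone in the partition, and a fit can be
re-judged at another partition without refitting.

### Component areas and indices

Each fitted component's area is the trapezoidal integral of the
offset-free component curve sampled on the measurement grid over
450–650 nm (not an analytic ±∞ integral — tails outside the band are not
counted; for interior peaks at typical widths the two agree to better
than 1e−4 because the trapezoidal rule is spectrally accurate on a
Gaussian whose derivatives vanish at the integration limits). The indices
are the unweighted combinations: `hb_index = AUC₅₃₉.₃₄ + AUC₅₇₇.₂`,
`bili_index = AUC₄₆₂.₉₂`, `spo2_index = AUC₅₇₇.₂ / AUC₅₆₈.₀₉`.

## Calibration and classification

Calibration curves map index to laboratory value with a fixed family per
analyte: Hb linear, TSB quadratic, SpO₂ quartic. Published sources for
this device family report only the families and goodness-of-fit, not
coefficients, so calibration is a fit-time artifact stored in a JSON file;
fits report Pearson r (linear) or degree-adjusted adjusted r² (polynomial).
SpO₂ is clamped to [0, 100] after evaluation with the clamp flagged, and
evaluation outside a model's fitted index range is flagged as
extrapolation. Classification uses strict inequalities for anemia
(Hb < 11 g/dL) and hypoxia (SpO₂ < 92%); jaundice uses a single
configurable TSB cut (default 15 mg/dL). A proper jaundice work-up uses an
age-in-hours nomogram; that is deliberately out of scope and the flag is
labelled accordingly.

## Synthetic-acquisition generator

The generator runs the model backwards from a known blood panel:

1. Index targets come from the inverses of fixed ground-truth calibration
   curves — Hb: `hb = 2 + 0.30·index`; TSB: `tsb = 1.2·x + 0.03·x²`
   (positive root inverted in closed form); SpO₂: the monotone quartic
   `40 + 30r − 5r² + 0.8r³ − 0.05r⁴` inverted numerically on
   r ∈ [0.001, 3.5]. Coefficients were chosen so physiological panels
   (Hb 5–22 g/dL, TSB 0–30 mg/dL, SpO₂ 60–100%) map onto positive,
   well-conditioned index ranges with peak absorbances of roughly 0.6–1.2,
   consistent with the gated operating range; the 577.2 nm component
   carries 75% of the hemoglobin index (the stronger oxy band), the
   539.34 nm component the rest, and the 568.09 nm area follows from the
   SpO₂ ratio.
2. Amplitudes are the target areas divided by each component's **unit
   trapezoidal area on the actual grid** (not the analytic `w√(2π)`), so
   a pipeline recovery reproduces the indices exactly. All generated
   widths are 15 nm, a typical fitted value; the offset is 0.02.
3. With gate targeting on (default), the 620 nm amplitude is solved so the
   total absorbance at 620 nm is 0.55, the center of the gate window.
4. Counts: dark = 100 ± 1 (seeded read noise), reference = dark + 40000
   (flat), `sample = dark + (reference − dark)·10^(−A)`. Detector noise is
   parameterized in equivalent absorbance units σ and applied to the
   sample counts with per-point standard deviation
   `ln10·(sample−dark)·σ`, which perturbs the recovered absorbance by ≈σ.
   Everything is a pure function of the (panel, σ, seed) triple.

What the generator does **not** emulate: tissue optics (melanin,
scattering phase functions, nail-plate layering), wavelength-dependent
reference shapes, correlated or Poisson detector noise, and subject
motion. Passing tests therefore demonstrate that the *algorithm* recovers
panels correctly under its own signal model at realistic noise, not that
the device achieves its clinical accuracy; the published clinical
correlations would require the patient dataset, which is unavailable.

## Validation statistics

* Regression: OLS of device on reference (`scipy.stats.linregress`),
  Pearson r, two-sided slope p.
* Bland–Altman: differences oriented `device − reference`; bias is their
  mean, SD the population form `√(Σ(xᵢ−µ)²/N)` (the printed version of
  this formula omits the square; the population SD is the only reading
  yielding a non-negative real), limits `bias ± 1.96·SD`.
* Repeatability: per-subject mean and population SD over k ≥ 2
  replicates; pooled SD is the RMS of per-subject SDs.
* Sample size: the Buderer diagnostic-test equations
  `n_sens = ⌈z²·SN(1−SN)/(W²·P)⌉`, `n_spec = ⌈z²·SP(1−SP)/(W²(1−P))⌉`,
  which with SN = 0.95, SP = 0.80, W = 0.05, P = 0.15, z = 1.96 give
  487 and 290.

## Problem sizes and numerical notes

The test suite and acceptance script use the native 426-point grid
throughout. Monte-Carlo sweeps use 50 seeds for noisy amplitude recovery,
200 subjects for the noisy-cohort correlations, 200 (tests) / 50 (script)
subjects for the noiseless roundtrip, and 30 seeds for the high-noise
rejection rate — sizes at which the checked statistics are stable to well
within their asserted margins. Degenerate inputs (empty spectra,
non-monotonic grids, non-positive dark-corrected signal, constant
calibration columns, fewer than two replicates) raise typed errors rather
than propagating NaNs.

## Known limitations

* The calibration families are fixed per analyte; there is no model
  selection.
* The jaundice flag is a flat TSB cut, not a nomogram risk zone.
* The acceptance rule judges only residual dispersion; a systematically
  biased but tight fit would pass.
* Indices assume the 568.09 nm area is strictly positive; anoxic spectra
  with a vanishing deoxy component would be rejected as degenerate rather
  than extrapolated.
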