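# neodrs

Simultaneous, non-invasive estimation of blood **hemoglobin** (Hb, g/dL),
**total serum bilirubin** (TSB, mg/dL) and **oxygen saturation** (SpO₂, %)
from a single visible-range diffuse-reflectance spectrum of the neonatal
nail bed — the measurement chain of a point-of-care screening device for
neonatal anemia, jaundice and hypoxia, implemented as a library plus a
`neodrs` command-line tool, with a synthetic-acquisition generator so every
stage can be exercised and validated without a spectrometer.

## The method

A measurement consists of three acquisitions on one wavelength grid
(450–650 nm at 0.47 nm): the nail-bed *sample*, a *dark* spectrum and a
*reference* from a standard diffuse scatterer. The processed spectrum is
the decadic absorbance

```
A(λ) = -log₁₀( (sample − dark) / (reference − dark) )
```

An amplitude gate requires `0.5 ≤ A(620 nm) ≤ 0.6` — the window that
corresponds to correct probe geometry; spectra outside it should be
re-acquired. The gated spectrum is then deconvolved into five Gaussian
components with **fixed centers** and free amplitudes `Aᵢ`, widths `wᵢ` and
one shared offset `y₀`:

```
A(λ) = y₀ + Σᵢ Aᵢ · exp( −0.5 ((λ − x_cᵢ)/wᵢ)² )

x_c ∈ { 462.92 (bilirubin), 539.34 (oxy-Hb Q band),
        568.09 (deoxy-Hb), 577.2 (oxy-Hb Q band), 620 (baseline) } nm
```

fitted by bounded nonlinear least squares on the mean squared residual.
A fit is **accepted** when at least a partition fraction (90, 95 or 98%)
of residuals lie within ±0.02 absorbance of the cumulative curve. From the
trapezoidal areas under the accepted components (the 620 nm baseline term
excluded), three instrument indices are formed

```
hb_index   = AUC₅₃₉.₃₄ + AUC₅₇₇.₂
bili_index = AUC₄₆₂.₉₂
spo2_index = AUC₅₇₇.₂ / AUC₅₆₈.₀₉
```

and mapped to blood values through per-analyte calibration curves (Hb
linear, TSB quadratic, SpO₂ quartic). The panel is classified with
anemia Hb < 11 g/dL, hypoxia SpO₂ < 92%, and jaundice TSB ≥ 15 mg/dL
(a single configurable cut, not an age-adjusted nomogram).

The package also implements the validation battery used for such devices:
simple linear regression, Bland–Altman agreement (bias ± 1.96·SD limits),
within-subject repeatability, and the Buderer diagnostic sample-size
equations.

## Worked example

```python
import numpy as np
from neodrs import (BloodPanel, Config, generate_spectrum, ground_truth_models,
                    make_truth, run_measurement_from_spectra)

# synthesize an acquisition from a sick neonate's known panel
truth = make_truth(BloodPanel(tsb=18.5, hb=9.8, spo2=88.0), sigma=0.005, seed=42)
sample, dark, reference = generate_spectrum(truth)

report = run_measurement_from_spectra(sample, dark, reference,
                                      ground_truth_models(), config=Config())
print("accepted:", report.accepted)
print(f"gate A(620) = {report.gate.absorbance_at_620:.3f}  "
      f"residual fraction = {report.deconvolution.residual_fraction:.3f}")
p = report.panel
print(f"panel: Hb {p.hb:.1f} g/dL  TSB {p.tsb:.1f} mg/dL  SpO2 {p.spo2:.1f} %")
c = report.classification
print(f"flags: anemia={c.anemia} jaundice={c.jaundice} hypoxia={c.hypoxia}")
```

prints

```
accepted: True
gate A(620) = 0.551  residual fraction = 1.000
panel: Hb 9.8 g/dL  TSB 18.7 mg/dL  SpO2 87.1 %
flags: anemia=True jaundice=True hypoxia=True
```

The gate value sits inside the [0.5, 0.6] window, every residual of the
five-Gaussian fit is within ±0.02 absorbance (fraction 1.000, so the
measurement is accepted at the 98% partition), and the recovered panel
matches the generating truth (18.5 / 9.8 / 88.0) to within the σ = 0.005
detector-noise level — flagging the subject anemic, jaundiced and hypoxic.

The same flow is available from the shell:

```sh
neodrs synth --n 20 --seed 1 --sigma 0.005 --out-dir cohort
neodrs measure --sample cohort/synth-0000_sample.csv \
               --dark cohort/synth-0000_dark.csv \
               --ref cohort/synth-0000_reference.csv \
               --calib calib.json --out report.json
neodrs batch --manifest cohort/manifest.csv --calib calib.json --out-dir reports
```

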