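"""Synthetic acquisition generator with known ground-truth blood panels.

The generator runs the measurement model forwards: a blood panel
(Hb, TSB, SpO2) is converted to the three instrument indices through the
*inverses* of a fixed set of ground-truth calibration curves, the indices
are realized as component amplitudes of the five-Gaussian absorbance model,
and the absorbance is converted back to detector counts

    sample = dark + (reference - dark) * 10**(-A)

with a flat reference, a small noisy dark, and optional detector noise on
the sample counts. Running the measurement pipeline on such a triple with
the same calibration file must return the generating panel (exactly for
zero noise), which makes every stage testable end to end without any real
acquisition.

The ground-truth calibration curves follow the device's families (Hb linear,
TSB quadratic, SpO2 quartic) with fixed documented coefficients chosen so
that physiological panels (Hb 5-22 g/dL, TSB 0-30 mg/dL, SpO2 60-100%) map
onto positive, invertible index ranges. They model nothing beyond that:
the generator emulates the device's own signal model, not tissue optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import CROP_NM, RESOLUTION_NM
from .deconvolve import BASELINE_CENTER_NM, CENTERS_NM, GaussianComponent, component_auc
from .errors import ValidationError
from .quantify import BloodPanel, CalibrationModel
from .spectra_io import RawSpectrum, WavelengthGrid

# ---------------------------------------------------------------------------
# Fixed generator constants
# ---------------------------------------------------------------------------

#: Width (Gaussian sigma, nm) of every generated component.
GEN_WIDTH_NM = 15.0

#: Scattering baseline offset added to every generated absorbance spectrum.
GEN_OFFSET = 0.02

#: Share of the hemoglobin index carried by the 577.2 nm component (the
#: stronger oxyhemoglobin Q band at physiological saturation); the 539.34 nm
#: component carries the rest, and the 568.09 nm amplitude follows from the
#: SpO2 ratio.
HB_577_SHARE = 0.75

#: Gate-targeting absorbance at 620 nm (center of the [0.5, 0.6] window).
GATE_TARGET = 0.55

#: Baseline-component amplitude when gate targeting is off.
DEFAULT_BASELINE_AMPLITUDE = 0.3

#: Flat reference signal above dark, in counts.
REFERENCE_COUNTS = 40000.0

#: Mean dark level in counts, with 1-count read noise.
DARK_COUNTS = 100.0
DARK_NOISE_SD = 1.0

#: Physiological panel bounds accepted by the generator.
PHYSIO_RANGES = {"hb": (5.0, 22.0), "tsb": (0.0, 30.0), "spo2": (60.0, 100.0)}

#: Ground-truth calibration coefficients, constant term first.
_HB_COEFFS = (2.0, 0.30)                       # hb = 2 + 0.30 * index
_TSB_COEFFS = (0.0, 1.2, 0.03)                 # tsb = 1.2 x + 0.03 x^2
_SPO2_COEFFS = (40.0, 30.0, -5.0, 0.8, -0.05)  # monotone quartic on [0, 3.5]

_SPO2_RATIO_BRACKET = (1e-3, 3.5)


def default_grid() -> WavelengthGrid:
    """The 450-650 nm grid at the detector's 0.47 nm resolution (426 points)."""
    return WavelengthGrid.regular(CROP_NM[0], CROP_NM[1], RESOLUTION_NM)


def ground_truth_models() -> dict[str, CalibrationModel]:
    """The fixed calibration models the generator inverts.

    Fitting a pipeline output against these models' forward evaluation must
    reproduce a generated cohort's panels; they double as the calibration
    file for end-to-end tests.
    """
    return {
        "Hb": CalibrationModel(
            analyte="Hb", family="linear", coefficients=_HB_COEFFS,
            index_range=(10.0, 67.0), diagnostics={"source": "synthetic ground truth"},
        ),
        "TSB": CalibrationModel(
            analyte="TSB", family="poly2", coefficients=_TSB_COEFFS,
            index_range=(0.0, 18.0), diagnostics={"source": "synthetic ground truth"},
        ),
        "SpO2": CalibrationModel(
            analyte="SpO2", family="poly4", coefficients=_SPO2_COEFFS,
            index_range=(0.5, 3.0), diagnostics={"source": "synthetic ground truth"},
        ),
    }


# ---------------------------------------------------------------------------
# Calibration inverses (panel -> index targets)
# ---------------------------------------------------------------------------

def _invert_hb(hb: float) -> float:
    c0, c1 = _HB_COEFFS
    return (hb - c0) / c1


def _invert_tsb(tsb: float) -> float:
    # positive root of c2 x^2 + c1 x - tsb = 0
    _, c1, c2 = _TSB_COEFFS
    return (-c1 + np.sqrt(c1 * c1 + 4.0 * c2 * tsb)) / (2.0 * c2)


def _invert_spo2(spo2: float) -> float:
    def f(r: float) -> float:
        return float(np.polynomial.polynomial.polyval(r, _SPO2_COEFFS)) - spo2

    return float(brentq(f, *_SPO2_RATIO_BRACKET, xtol=1e-12))


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic acquisition: the panel, the generating
    model parameters derived from it, the noise level and the seed."""

    panel: BloodPanel
    amplitudes: tuple[float, ...]   # ordered as CENTERS_NM
    widths: tuple[float, ...]
    offset: float
    sigma: float
    seed: int


@dataclass(frozen=True)
class CohortSpec:
    """Cohort description: panel distributions (uniform over ranges inside
    the physiological bounds), noise level sigma (equivalent absorbance
    units), gate targeting, and the master seed."""

    n: int
    hb_range: tuple[float, float] = (6.0, 21.0)
    tsb_range: tuple[float, float] = (0.5, 28.0)
    spo2_range: tuple[float, float] = (70.0, 100.0)
    sigma: float = 0.0
    gate_targeting: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        for name, rng in (("hb", self.hb_range), ("tsb", self.tsb_range),
                          ("spo2", self.spo2_range)):
            lo, hi = PHYSIO_RANGES[name]
            if not (lo <= rng[0] <= rng[1] <= hi):
                raise ValidationError(
                    f"{name} range {rng} outside physiological bounds ({lo}, {hi})"
                )
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")


def make_truth(
    panel: BloodPanel,
    sigma: float = 0.0,
    seed: int = 0,
    grid: WavelengthGrid | None = None,
    gate_targeting: bool = True,
) -> TruthRecord:
    """Derive generating amplitudes for a panel via the calibration inverses.

    Index targets: hb_index from the linear inverse, bili_index from the
    quadratic inverse, spo2 ratio from the quartic inverse. The hemoglobin
    index is split HB_577_SHARE : (1 - HB_577_SHARE) between the 577.2 and
    539.34 nm components; the 568.09 nm area is the 577.2 nm area divided by
    the ratio. Amplitudes are areas divided by each component's unit
    trapezoidal area on the actual grid, so pipeline-recovered indices match
    the targets exactly. With gate targeting on, the 620 nm amplitude is
    solved so the total absorbance at 620 nm equals GATE_TARGET.
    """
    for name in ("hb", "tsb", "spo2"):
        lo, hi = PHYSIO_RANGES[name]
        v = getattr(panel, name)
        if not lo <= v <= hi:
            raise ValidationError(f"{name}={v} outside physiological range ({lo}, {hi})")
    grid = grid or default_grid()

    hb_index = _invert_hb(panel.hb)
    bili_index = _invert_tsb(panel.tsb)
    ratio = _invert_spo2(panel.spo2)

    auc_targets = {
        462.92: bili_index,
        539.34: (1.0 - HB_577_SHARE) * hb_index,
        577.2: HB_577_SHARE * hb_index,
    }
    auc_targets[568.09] = auc_targets[577.2] / ratio

    unit_auc = {
        c: component_auc(GaussianComponent(c, 1.0, GEN_WIDTH_NM), grid)
        for c in CENTERS_NM
    }
    amps = {c: auc_targets[c] / unit_auc[c] for c in auc_targets}

    if gate_targeting:
        others_at_620 = sum(
            a * np.exp(-0.5 * ((BASELINE_CENTER_NM - c) / GEN_WIDTH_NM) ** 2)
            for c, a in amps.items()
        )
        a620 = GATE_TARGET - GEN_OFFSET - others_at_620
        if a620 <= 0:
            raise ValidationError(
                "gate targeting infeasible: chromophore absorbance at 620 nm "
                "already exceeds the gate target"
            )
    else:
        a620 = DEFAULT_BASELINE_AMPLITUDE
    amps[BASELINE_CENTER_NM] = a620

    return TruthRecord(
        panel=panel,
        amplitudes=tuple(float(amps[c]) for c in CENTERS_NM),
        widths=(GEN_WIDTH_NM,) * 5,
        offset=GEN_OFFSET,
        sigma=float(sigma),
        seed=int(seed),
    )


def target_absorbance(truth: TruthRecord, grid: WavelengthGrid) -> np.ndarray:
    """The noiseless absorbance spectrum encoded by a truth record."""
    total = np.full(len(grid), truth.offset)
    for c, a, w in zip(CENTERS_NM, truth.amplitudes, truth.widths):
        z = (grid.values - c) / w
        total += a * np.exp(-0.5 * z * z)
    return total


def generate_spectrum(
    truth: TruthRecord, grid: WavelengthGrid | None = None
) -> tuple[RawSpectrum, RawSpectrum, RawSpectrum]:
    """Render a truth record as a (sample, dark, reference) count triple.

    The dark spectrum is a small constant plus seeded read noise; the
    reference sits a flat REFERENCE_COUNTS above dark; the sample encodes
    the target absorbance. Detector noise of equivalent-absorbance sigma is
    added to the sample counts as Gaussian noise with per-point standard
    deviation ln(10) * (sample - dark) * sigma, which perturbs the recovered
    absorbance by ~sigma for small sigma. The triple is a pure function of
    (truth, grid).
    """
    grid = grid or default_grid()
    rng = np.random.default_rng(truth.seed)
    n = len(grid)

    dark_counts = DARK_COUNTS + rng.normal(0.0, DARK_NOISE_SD, n)
    dark_counts = np.clip(dark_counts, 0.0, None)
    reference_counts = dark_counts + REFERENCE_COUNTS

    signal = REFERENCE_COUNTS * 10.0 ** (-target_absorbance(truth, grid))
    if truth.sigma > 0:
        signal = signal + rng.normal(0.0, np.log(10.0) * signal * truth.sigma)
        signal = np.clip(signal, 1e-6, None)
    sample_counts = dark_counts + signal

    common = dict(integration_time_ms=3000, boxcar_width=0)
    return (
        RawSpectrum(grid, sample_counts, role="sample", **common),
        RawSpectrum(grid, dark_counts, role="dark", **common),
        RawSpectrum(grid, reference_counts, role="reference", **common),
    )


def generate_cohort(
    spec: CohortSpec, grid: WavelengthGrid | None = None
) -> tuple[list[tuple[RawSpectrum, RawSpectrum, RawSpectrum]], pd.DataFrame]:
    """Draw a cohort of truth panels and render each as a count triple.

    Panels are uniform over the spec's ranges; each subject gets its own
    seed derived from the master seed. Returns the list of triples and a
    truth table with one row per subject (subject_id, hb, tsb, spo2, sigma,
    seed). Identical specs reproduce identical outputs.
    """
    grid = grid or default_grid()
    master = np.random.default_rng(spec.seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=spec.n)
    hb = master.uniform(*spec.hb_range, size=spec.n)
    tsb = master.uniform(*spec.tsb_range, size=spec.n)
    spo2 = master.uniform(*spec.spo2_range, size=spec.n)

    triples = []
    rows = []
    for i in range(spec.n):
        panel = BloodPanel(tsb=float(tsb[i]), hb=float(hb[i]), spo2=float(spo2[i]))
        truth = make_truth(
            panel,
            sigma=spec.sigma,
            seed=int(subject_seeds[i]),
            grid=grid,
            gate_targeting=spec.gate_targeting,
        )
        triples.append(generate_spectrum(truth, grid))
        rows.append(
            {
                "subject_id": f"synth-{i:04d}",
                "hb": panel.hb,
                "tsb": panel.tsb,
                "spo2": panel.spo2,
                "sigma": spec.sigma,
                "seed": int(subject_seeds[i]),
            }
        )
    return triples, pd.DataFrame(rows)
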