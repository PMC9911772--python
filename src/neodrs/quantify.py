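"""Instrument indices, calibration mapping and disease classification.

From an accepted deconvolution, three scalar *instrument indices* are
formed from the component areas (the 620 nm baseline component never
participates):

    hb_index   = AUC(539.34) + AUC(577.2)      total oxyhemoglobin Q bands
    bili_index = AUC(462.92)                   bilirubin feature
    spo2_index = AUC(577.2) / AUC(568.09)      oxy/deoxy ratio

Each index maps to a blood value through an analyte-specific calibration
curve fitted against laboratory gold-standard values: hemoglobin is linear
in its index, total serum bilirubin quadratic, and SpO2 quartic. The
resulting panel is classified with fixed thresholds: anemia Hb < 11 g/dL,
hypoxia SpO2 < 92%, and jaundice TSB at or above a single configurable cut
(default 15 mg/dL; this is deliberately not an age-adjusted nomogram).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .config import ClassifyConfig
from .deconvolve import BASELINE_CENTER_NM, DeconvolutionResult, component_auc
from .errors import CalibrationError, DegenerateDataError, ValidationError
from .spectra_io import PairedTable, WavelengthGrid

ANALYTES = ("Hb", "TSB", "SpO2")

#: Fixed polynomial family (degree) per analyte.
FAMILIES: dict[str, tuple[str, int]] = {
    "Hb": ("linear", 1),
    "TSB": ("poly2", 2),
    "SpO2": ("poly4", 4),
}


@dataclass(frozen=True)
class InstrumentIndices:
    """The three AUC-derived scalar indices."""

    hb_index: float
    bili_index: float
    spo2_index: float

    def __post_init__(self):
        if self.hb_index < 0 or self.bili_index < 0:
            raise ValidationError("area-based indices must be non-negative")
        if not np.isfinite(self.spo2_index) or self.spo2_index < 0:
            raise ValidationError("spo2 index must be finite and non-negative")

    def for_analyte(self, analyte: str) -> float:
        return {
            "Hb": self.hb_index,
            "TSB": self.bili_index,
            "SpO2": self.spo2_index,
        }[analyte]


@dataclass(frozen=True)
class CalibrationModel:
    """Polynomial map from instrument index to laboratory value.

    ``coefficients`` are ordered from the constant term upward. The family
    is fixed per analyte (Hb linear, TSB quadratic, SpO2 quartic).
    ``index_range`` is the index interval seen during fitting; evaluation
    outside it is allowed but flagged as extrapolation.
    """

    analyte: str
    family: str
    coefficients: tuple[float, ...]
    index_range: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.analyte not in FAMILIES:
            raise ValidationError(f"unknown analyte {self.analyte!r}")
        family, degree = FAMILIES[self.analyte]
        if self.family != family:
            raise ValidationError(
                f"{self.analyte} requires family {family!r}, got {self.family!r}"
            )
        if len(self.coefficients) != degree + 1:
            raise ValidationError(
                f"{self.family} needs {degree + 1} coefficients, "
                f"got {len(self.coefficients)}"
            )

    def evaluate(self, index: float) -> float:
        return float(np.polynomial.polynomial.polyval(index, self.coefficients))

    def in_range(self, index: float) -> bool:
        lo, hi = self.index_range
        return lo <= index <= hi

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "family": self.family,
            "coefficients": list(self.coefficients),
            "index_range": list(self.index_range),
            "diagnostics": self.diagnostics,
        }


@dataclass(frozen=True)
class BloodPanel:
    """Estimated blood values: TSB mg/dL, Hb g/dL, SpO2 %."""

    tsb: float
    hb: float
    spo2: float
    spo2_clamped: bool = False
    extrapolated: tuple[str, ...] = ()

    def __post_init__(self):
        for name in ("tsb", "hb", "spo2"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return {
            "tsb_mg_dl": self.tsb,
            "hb_g_dl": self.hb,
            "spo2_percent": self.spo2,
            "spo2_clamped": self.spo2_clamped,
            "extrapolated": list(self.extrapolated),
        }


@dataclass(frozen=True)
class ClassificationResult:
    """Disease flags with the thresholds used."""

    anemia: bool
    hypoxia: bool
    jaundice: bool
    thresholds: ClassifyConfig

    def to_dict(self) -> dict:
        return {
            "anemia": self.anemia,
            "hypoxia": self.hypoxia,
            "jaundice": self.jaundice,
            "thresholds": self.thresholds.model_dump(),
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_indices(
    result: DeconvolutionResult,
    grid: WavelengthGrid,
    force: bool = False,
) -> InstrumentIndices:
    """Form the three instrument indices from component areas.

    The 620 nm component is excluded by construction. Requires an accepted
    fit unless ``force`` is set (e.g. for diagnostics on rejected spectra).
    """
    if not result.accepted and not force:
        raise ValidationError(
            "deconvolution was rejected; pass force=True to compute indices anyway"
        )
    auc = {
        c.center: component_auc(c, grid)
        for c in result.components
        if c.center != BASELINE_CENTER_NM
    }
    denom = auc[568.09]
    if denom <= 0:
        raise DegenerateDataError(
            "deoxyhemoglobin component area is non-positive; fit is degenerate"
        )
    return InstrumentIndices(
        hb_index=auc[539.34] + auc[577.2],
        bili_index=auc[462.92],
        spo2_index=auc[577.2] / denom,
    )


def fit_calibration(table: PairedTable, analyte: str) -> CalibrationModel:
    """Ordinary least-squares fit of laboratory value on instrument index.

    The ``device`` column of the table holds the index, ``reference`` the
    laboratory value. The polynomial family is fixed by the analyte.
    Diagnostics carry Pearson r (linear family) or the degree-adjusted
    adjusted r-squared (polynomial families), plus n.
    """
    if analyte not in FAMILIES:
        raise ValidationError(f"unknown analyte {analyte!r}")
    family, degree = FAMILIES[analyte]
    x, y = table.device, table.reference
    n = x.size
    if n < degree + 2:
        raise ValidationError(
            f"{analyte} ({family}) needs at least {degree + 2} rows, got {n}"
        )
    if np.ptp(x) == 0:
        raise DegenerateDataError("all instrument indices are equal")

    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    diagnostics: dict = {"n": int(n), "r_squared": r2}
    if family == "linear":
        diagnostics["r"] = float(stats.pearsonr(x, y).statistic)
    else:
        p = degree
        diagnostics["adjusted_r_squared"] = (
            1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else float("nan")
        )
    return CalibrationModel(
        analyte=analyte,
        family=family,
        coefficients=tuple(float(c) for c in coeffs),
        index_range=(float(x.min()), float(x.max())),
        diagnostics=diagnostics,
    )


def apply_calibration(
    indices: InstrumentIndices,
    models: dict[str, CalibrationModel],
) -> BloodPanel:
    """Evaluate each analyte's calibration polynomial at its index.

    SpO2 is clamped to [0, 100] after evaluation (polynomials are unbounded,
    the saturation is not); clamping and extrapolation beyond any model's
    fitted index range are flagged on the returned panel.
    """
    missing = [a for a in ANALYTES if a not in models]
    if missing:
        raise CalibrationError(f"missing calibration model(s) for {missing}")
    extrapolated = []
    values = {}
    for analyte in ANALYTES:
        model = models[analyte]
        if model.analyte != analyte:
            raise CalibrationError(
                f"model labelled {model.analyte!r} supplied for {analyte!r}"
            )
        idx = indices.for_analyte(analyte)
        if not model.in_range(idx):
            extrapolated.append(analyte)
        values[analyte] = model.evaluate(idx)

    spo2 = values["SpO2"]
    clamped = not 0.0 <= spo2 <= 100.0
    return BloodPanel(
        tsb=values["TSB"],
        hb=values["Hb"],
        spo2=float(np.clip(spo2, 0.0, 100.0)),
        spo2_clamped=clamped,
        extrapolated=tuple(extrapolated),
    )


def classify(
    panel: BloodPanel, thresholds: ClassifyConfig | None = None
) -> ClassificationResult:
    """Flag anemia (Hb < 11), hypoxia (SpO2 < 92, strict) and jaundice
    (TSB >= cut, default 15 mg/dL)."""
    thresholds = thresholds or ClassifyConfig()
    return ClassificationResult(
        anemia=bool(panel.hb < thresholds.hb_anemia),
        hypoxia=bool(panel.spo2 < thresholds.spo2_hypoxia),
        jaundice=bool(panel.tsb >= thresholds.tsb_jaundice),
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Calibration file I/O
# ---------------------------------------------------------------------------

def save_calibration(models: dict[str, CalibrationModel], path: str | Path) -> None:
    """Write the per-analyte calibration models to a JSON file."""
    payload = [models[a].to_dict() for a in ANALYTES if a in models]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_calibration(path: str | Path) -> dict[str, CalibrationModel]:
    """Load calibration models from JSON; validates families and analytes."""
    path = Path(path)
    if not path.exists():
        raise CalibrationError(f"calibration file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CalibrationError(f"malformed calibration file {path}: {exc}") from exc
    models = {}
    for entry in payload:
        model = CalibrationModel(
            analyte=entry["analyte"],
            family=entry["family"],
            coefficients=tuple(entry["coefficients"]),
            index_range=tuple(entry["index_range"]),
            diagnostics=entry.get("diagnostics", {}),
        )
        models[model.analyte] = model
    return models
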