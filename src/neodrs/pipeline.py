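"""End-to-end measurement workflow.

One measurement runs the stages in device order:

    read -> align -> boxcar -> absorbance -> gate -> fit -> accept
         -> indices -> calibrate -> classify

Rejected acquisitions (gate failure in strict mode, or residual fraction
below the partition) still produce a structured report naming the failing
criterion so the operator can re-acquire; they carry no blood panel.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .config import Config
from .deconvolve import DeconvolutionResult, fit_five_gaussians
from .errors import CalibrationError, NeodrsError, ValidationError
from .preprocess import (
    GateResult,
    boxcar_smooth,
    check_gate,
    compute_absorbance,
)
from .quantify import (
    BloodPanel,
    CalibrationModel,
    ClassificationResult,
    InstrumentIndices,
    apply_calibration,
    classify,
    compute_indices,
    load_calibration,
)
from .spectra_io import (
    PairedTable,
    RawSpectrum,
    align_to_common_grid,
    read_spectrum,
)
from .valstats import BlandAltmanReport, RegressionReport, bland_altman, linear_regression

logger = logging.getLogger("neodrs.pipeline")

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class MeasurementReport:
    """Structured outcome of one measurement, accepted or rejected."""

    subject_id: str
    accepted: bool
    rejection_reason: str | None
    gate: GateResult
    deconvolution: DeconvolutionResult
    indices: InstrumentIndices | None
    panel: BloodPanel | None
    classification: ClassificationResult | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "subject_id": self.subject_id,
            "accepted": self.accepted,
            "rejection_reason": self.rejection_reason,
            "gate": {
                "absorbance_at_620": self.gate.absorbance_at_620,
                "lower": self.gate.lower,
                "upper": self.gate.upper,
                "passed": self.gate.passed,
            },
            "deconvolution": {
                "mse": self.deconvolution.mse,
                "residual_fraction": self.deconvolution.residual_fraction,
                "accepted": self.deconvolution.accepted,
                "partition": self.deconvolution.partition,
            },
            "indices": None
            if self.indices is None
            else {
                "hb_index": self.indices.hb_index,
                "bili_index": self.indices.bili_index,
                "spo2_index": self.indices.spo2_index,
            },
            "panel": None if self.panel is None else self.panel.to_dict(),
            "classification": None
            if self.classification is None
            else self.classification.to_dict(),
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _config_hash(config: Config) -> str:
    return hashlib.sha256(
        config.model_dump_json().encode()
    ).hexdigest()[:12]


def _stage(name: str, start: float, **scalars) -> None:
    detail = " ".join(f"{k}={v:.6g}" if isinstance(v, float) else f"{k}={v}"
                      for k, v in scalars.items())
    logger.info("stage=%s elapsed_ms=%.1f %s", name, (time.perf_counter() - start) * 1e3, detail)


def run_measurement_from_spectra(
    sample: RawSpectrum,
    dark: RawSpectrum,
    reference: RawSpectrum,
    models: dict[str, CalibrationModel],
    config: Config | None = None,
    subject_id: str = "",
    provenance: dict | None = None,
) -> MeasurementReport:
    """Run the measurement chain on already-loaded spectra."""
    config = config or Config()
    prov = {
        "config_hash": _config_hash(config),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **(provenance or {}),
    }

    t = time.perf_counter()
    sample, dark, reference = align_to_common_grid([sample, dark, reference])
    _stage("align", t, n_points=len(sample.grid))

    t = time.perf_counter()
    if config.boxcar.width > 0:
        sample = boxcar_smooth(sample, config.boxcar.width)
        dark = boxcar_smooth(dark, config.boxcar.width)
        reference = boxcar_smooth(reference, config.boxcar.width)
    _stage("boxcar", t, width=config.boxcar.width)

    t = time.perf_counter()
    absorbance = compute_absorbance(sample, dark, reference, crop=config.crop)
    _stage("absorbance", t, n_points=len(absorbance.grid))

    t = time.perf_counter()
    gate = check_gate(absorbance, config.gate)
    _stage("gate", t, a620=gate.absorbance_at_620, passed=gate.passed)

    t = time.perf_counter()
    fit = fit_five_gaussians(absorbance, config.fit)
    _stage("fit", t, mse=fit.mse, residual_fraction=fit.residual_fraction)

    rejection = None
    if not gate.passed and config.gate.strict:
        rejection = (
            f"gate: absorbance {gate.absorbance_at_620:.3f} at "
            f"{config.gate.wavelength_nm:g} nm outside [{gate.lower}, {gate.upper}]; "
            "re-acquire with the probe held perpendicular at the intended distance"
        )
    elif not fit.accepted:
        rejection = (
            f"residual_fraction {fit.residual_fraction:.4f} < partition "
            f"{fit.partition:.2f}; re-acquire (noisy or distorted spectrum)"
        )

    indices = panel = label = None
    if rejection is None:
        t = time.perf_counter()
        indices = compute_indices(fit, absorbance.grid)
        panel = apply_calibration(indices, models)
        label = classify(panel, config.classify)
        _stage("quantify", t, hb=panel.hb, tsb=panel.tsb, spo2=panel.spo2)

    return MeasurementReport(
        subject_id=subject_id,
        accepted=rejection is None,
        rejection_reason=rejection,
        gate=gate,
        deconvolution=fit,
        indices=indices,
        panel=panel,
        classification=label,
        provenance=prov,
    )


def run_measurement(
    sample_path: str | Path,
    dark_path: str | Path,
    reference_path: str | Path,
    calibration_path: str | Path,
    config: Config | str | Path | None = None,
    subject_id: str = "",
) -> MeasurementReport:
    """Run one measurement from files on disk.

    The calibration file is loaded (and validated) before any spectra are
    read or fitted, so a missing calibration fails fast.
    """
    from .config import load_config

    models = load_calibration(calibration_path)
    if not isinstance(config, Config):
        config = load_config(config)

    spectra = {}
    for role, path in (
        ("sample", sample_path),
        ("dark", dark_path),
        ("reference", reference_path),
    ):
        spectra[role] = read_spectrum(path, role=role)  # type: ignore[arg-type]

    return run_measurement_from_spectra(
        spectra["sample"],
        spectra["dark"],
        spectra["reference"],
        models,
        config=config,
        subject_id=subject_id,
        provenance={
            "sample_file": str(sample_path),
            "dark_file": str(dark_path),
            "reference_file": str(reference_path),
            "calibration_file": str(calibration_path),
        },
    )


@dataclass(frozen=True)
class BatchReport:
    """Per-subject reports plus conservation counts."""

    reports: tuple[MeasurementReport, ...]
    errors: tuple[dict, ...]
    processed: int
    accepted: int
    rejected: int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "accepted": r.accepted,
                    "rejection_reason": r.rejection_reason,
                    "residual_fraction": r.deconvolution.residual_fraction,
                    "hb": r.panel.hb if r.panel else None,
                    "tsb": r.panel.tsb if r.panel else None,
                    "spo2": r.panel.spo2 if r.panel else None,
                }
            )
        return pd.DataFrame(rows)


def run_batch(
    manifest_path: str | Path,
    calibration_path: str | Path,
    config: Config | str | Path | None = None,
) -> BatchReport:
    """Process a manifest CSV with columns subject_id, sample, dark, reference.

    Paths are resolved relative to the manifest's directory. A malformed row
    is recorded as a row-level error and the batch continues. An empty
    manifest yields an empty report (with a warning).
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "sample", "dark", "reference"}
    if len(manifest) and not required.issubset(manifest.columns):
        raise ValidationError(
            f"manifest must have columns {sorted(required)}, got {list(manifest.columns)}"
        )
    if manifest.empty:
        logger.warning("empty manifest %s: nothing to process", manifest_path)
        return BatchReport(reports=(), errors=(), processed=0, accepted=0, rejected=0)

    reports: list[MeasurementReport] = []
    errors: list[dict] = []
    for i, row in manifest.iterrows():
        try:
            report = run_measurement(
                base / str(row["sample"]),
                base / str(row["dark"]),
                base / str(row["reference"]),
                calibration_path,
                config=config,
                subject_id=str(row["subject_id"]),
            )
            reports.append(report)
        except (NeodrsError, OSError) as exc:
            errors.append({"row": int(i), "subject_id": str(row.get("subject_id", "?")),
                           "error": str(exc)})
    accepted = sum(r.accepted for r in reports)
    return BatchReport(
        reports=tuple(reports),
        errors=tuple(errors),
        processed=len(reports),
        accepted=accepted,
        rejected=len(reports) - accepted,
    )


def validate_device(
    pairs: dict[str, PairedTable],
) -> dict[str, dict]:
    """Per-analyte regression + Bland-Altman validation battery.

    ``pairs`` maps analyte label to a device-vs-reference table; analytes
    with no table are reported as skipped.
    """
    out: dict[str, dict] = {}
    for analyte in ("Hb", "TSB", "SpO2"):
        table = pairs.get(analyte)
        if table is None or len(table) < 3:
            out[analyte] = {"skipped": True, "reason": "fewer than 3 pairs supplied"}
            continue
        reg: RegressionReport = linear_regression(table)
        ba: BlandAltmanReport = bland_altman(table)
        out[analyte] = {
            "skipped": False,
            "regression": reg.to_dict(),
            "bland_altman": ba.to_dict(),
        }
    return out
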