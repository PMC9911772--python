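"""Pipeline configuration.

All tunables of the measurement chain live here with the device's published
operating values as defaults: the absorbance gate window [0.5, 0.6] at
620 nm, boxcar width 2, the ±0.02 residual tolerance with the 98% partition,
and the disease thresholds (anemia Hb < 11 g/dL, hypoxia SpO2 < 92%,
jaundice TSB >= 15 mg/dL).

Configuration files are TOML with one table per section::

    [gate]
    lower = 0.5
    upper = 0.6
    wavelength_nm = 620.0
    strict = false

    [boxcar]
    width = 2

    [fit]
    tolerance = 0.02
    partition = 0.98
    width_bounds = [1.0, 60.0]
    max_iter = 2000

    [classify]
    hb_anemia = 11.0
    spo2_hypoxia = 92.0
    tsb_jaundice = 15.0
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

#: Working wavelength band in nm; spectra are cropped to this interval.
CROP_NM: tuple[float, float] = (450.0, 650.0)

#: Native detector sampling interval in nm.
RESOLUTION_NM: float = 0.47


class GateConfig(BaseModel):
    """Absorbance amplitude gate that checks probe geometry."""

    lower: float = 0.5
    upper: float = 0.6
    wavelength_nm: float = 620.0
    strict: bool = False

    @model_validator(mode="after")
    def _ordered(self):
        if not self.lower <= self.upper:
            raise ValueError("gate.lower must not exceed gate.upper")
        return self


class BoxcarConfig(BaseModel):
    """Centered running-average smoothing; width w means a (2w+1)-point
    window. Width 0 disables smoothing."""

    width: int = Field(default=2, ge=0)


class FitSettings(BaseModel):
    """Five-Gaussian deconvolution settings.

    ``tolerance`` is the residual band in absorbance units; ``partition`` is
    the fraction of points that must fall inside it for acceptance
    (selectable 0.90 / 0.95 / 0.98).
    """

    tolerance: float = Field(default=0.02, gt=0)
    partition: float = Field(default=0.98, gt=0, le=1)
    width_bounds: tuple[float, float] = (1.0, 60.0)
    amplitude_bound: float = Field(default=10.0, gt=0)
    max_iter: int = Field(default=2000, ge=1)

    @model_validator(mode="after")
    def _bounds_ordered(self):
        lo, hi = self.width_bounds
        if not 0 < lo < hi:
            raise ValueError("fit.width_bounds must be positive and ordered")
        return self


class ClassifyConfig(BaseModel):
    """Disease thresholds. Anemia and hypoxia use strict ``<``; jaundice
    uses ``>=`` against a single TSB cut (not an age-adjusted nomogram)."""

    hb_anemia: float = 11.0
    spo2_hypoxia: float = 92.0
    tsb_jaundice: float = 15.0


class Config(BaseModel):
    """Top-level pipeline configuration."""

    gate: GateConfig = GateConfig()
    boxcar: BoxcarConfig = BoxcarConfig()
    fit: FitSettings = FitSettings()
    classify: ClassifyConfig = ClassifyConfig()
    crop: tuple[float, float] = CROP_NM


def load_config(path: str | Path | None) -> Config:
    """Load a TOML configuration file; ``None`` returns the defaults."""
    if path is None:
        return Config()
    with open(path, "rb") as fh:
        return Config.model_validate(tomllib.load(fh))
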