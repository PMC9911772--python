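"""Spectrum and paired-table I/O.

The canonical on-disk dialect is a two-column CSV with header
``wavelength_nm,intensity`` (``wavelength_nm,value`` for processed spectra)
and ``#``-prefixed metadata lines carrying the acquisition role, integration
time and boxcar width. A headerless two-column dialect is accepted on read
for raw spectrograph exports.

Paired calibration/validation tables are CSV with header
``subject_id,device,reference``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .config import CROP_NM
from .errors import (
    GridError,
    InsufficientOverlapError,
    SpectrumParseError,
    ValidationError,
)

Role = Literal["sample", "dark", "reference"]
_ROLES = ("sample", "dark", "reference")

#: Minimum shared wavelength span (nm) required to align spectra.
MIN_OVERLAP_NM = 100.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise GridError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise GridError("wavelength grid contains non-finite values")
        if np.any(np.diff(values) <= 0):
            raise GridError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def covers(self, wavelength: float) -> bool:
        lo, hi = self.span
        return lo <= wavelength <= hi

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        """Regular grid from ``start`` to at most ``stop`` with spacing ``step``."""
        n = int(np.floor((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))


@dataclass(frozen=True)
class RawSpectrum:
    """Detector counts on a wavelength grid with its acquisition role."""

    grid: WavelengthGrid
    intensities: np.ndarray
    role: Role = "sample"
    integration_time_ms: int = 3000
    boxcar_width: int = 2

    def __post_init__(self):
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", intensities)
        if intensities.shape != (len(self.grid),):
            raise ValidationError("intensity length does not match grid length")
        if not np.all(np.isfinite(intensities)):
            raise ValidationError("intensities must be finite")
        if np.any(intensities < 0):
            raise ValidationError("detector counts must be non-negative")
        if self.role not in _ROLES:
            raise ValidationError(f"role must be one of {_ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class PairedTable:
    """Device-versus-laboratory value pairs for one analyte.

    ``data`` has columns ``subject_id``, ``device``, ``reference``. For
    calibration use, ``device`` holds the instrument index rather than a
    blood value; the statistics do not care.
    """

    data: pd.DataFrame
    analyte: str = ""
    units: str = ""

    def __post_init__(self):
        required = {"subject_id", "device", "reference"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"paired table missing columns: {sorted(missing)}")
        used = self.data[["device", "reference"]]
        if used.isna().any().any():
            raise ValidationError("paired table contains missing values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def device(self) -> np.ndarray:
        return self.data["device"].to_numpy(dtype=float)

    @property
    def reference(self) -> np.ndarray:
        return self.data["reference"].to_numpy(dtype=float)


def read_paired_table(path: str | Path, analyte: str = "", units: str = "") -> PairedTable:
    """Read a ``subject_id,device,reference`` CSV."""
    return PairedTable(pd.read_csv(path), analyte=analyte, units=units)


def write_paired_table(table: PairedTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Spectrum files
# ---------------------------------------------------------------------------

def read_spectrum(
    path: str | Path,
    dialect: str = "csv",
    role: Role | None = None,
) -> RawSpectrum:
    """Read a two-column spectrum file.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"csv"`` (canonical, with header and ``#`` metadata lines),
        ``"tsv"`` (same but tab-separated) or ``"headerless"``
        (two whitespace/comma-separated numeric columns, no header).
    role
        Acquisition role; overrides any role stored in the file's metadata.

    Raises
    ------
    SpectrumParseError
        Non-numeric cell (message names the line number) or unknown dialect.
    GridError
        Non-monotonic or duplicated wavelengths.
    """
    path = Path(path)
    if dialect not in {"csv", "tsv", "headerless"}:
        raise SpectrumParseError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","

    meta: dict[str, str] = {}
    wavelengths: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if dialect == "headerless":
                parts = line.replace(",", " ").split()
            else:
                parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path.name}:{lineno}: expected two columns")
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError:
                if not wavelengths and dialect != "headerless":
                    continue  # header row
                raise SpectrumParseError(
                    f"{path.name}:{lineno}: non-numeric cell in {parts[:2]}"
                ) from None
            wavelengths.append(w)
            values.append(v)

    if not wavelengths:
        raise SpectrumParseError(f"{path.name}: no data rows")
    grid = WavelengthGrid(np.array(wavelengths))
    resolved_role: Role = role or meta.get("role", "sample")  # type: ignore[assignment]
    return RawSpectrum(
        grid=grid,
        intensities=np.array(values),
        role=resolved_role,
        integration_time_ms=int(meta.get("integration_time_ms", 3000)),
        boxcar_width=int(meta.get("boxcar_width", 2)),
    )


def write_spectrum(spectrum, path: str | Path, value_name: str | None = None) -> None:
    """Write a spectrum in the canonical CSV dialect.

    Accepts a :class:`RawSpectrum` (column ``intensity``) or any object with
    ``grid`` and ``absorbance`` attributes (column ``value``). Values are
    written with 9 significant digits so a read-back round-trip is exact at
    that precision.
    """
    path = Path(path)
    if hasattr(spectrum, "intensities"):
        values = spectrum.intensities
        name = value_name or "intensity"
        header_meta = [
            f"# role = {spectrum.role}",
            f"# integration_time_ms = {spectrum.integration_time_ms}",
            f"# boxcar_width = {spectrum.boxcar_width}",
        ]
    elif hasattr(spectrum, "absorbance"):
        values = spectrum.absorbance
        name = value_name or "value"
        header_meta = ["# role = processed"]
    else:
        raise ValidationError("object is not a spectrum")
    if len(values) == 0:
        raise ValidationError("refusing to write an empty spectrum")

    lines = header_meta + [f"wavelength_nm,{name}"]
    lines += [
        f"{w:.9g},{v:.9g}" for w, v in zip(spectrum.grid.values, values)
    ]
    path.write_text("\n".join(lines) + "\n")


def align_to_common_grid(spectra: Sequence[RawSpectrum]) -> list[RawSpectrum]:
    """Linearly interpolate spectra onto a shared grid.

    The target grid is the first spectrum's grid restricted to the
    intersection of all spans and to the working band ``[450, 650]`` nm.
    Spectra already on the target grid are returned unchanged, which makes
    the operation idempotent.
    """
    if not spectra:
        raise ValidationError("no spectra to align")
    lo = max(s.grid.span[0] for s in spectra)
    hi = min(s.grid.span[1] for s in spectra)
    lo, hi = max(lo, CROP_NM[0]), min(hi, CROP_NM[1])
    if hi - lo < MIN_OVERLAP_NM:
        raise InsufficientOverlapError(
            f"shared span {max(hi - lo, 0):.1f} nm < {MIN_OVERLAP_NM:.0f} nm"
        )
    base = spectra[0].grid.values
    target = WavelengthGrid(base[(base >= lo) & (base <= hi)])

    out = []
    for s in spectra:
        if np.array_equal(s.grid.values, target.values):
            out.append(s)
        else:
            out.append(
                replace(
                    s,
                    grid=target,
                    intensities=np.interp(target.values, s.grid.values, s.intensities),
                )
            )
    return out
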