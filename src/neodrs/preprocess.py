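"""Raw-triple to absorbance conversion and the amplitude gate.

A measurement consists of three acquisitions on one grid: the nail-bed
``sample``, a ``dark`` spectrum (source off, ambient light only) and a
``reference`` from a standard diffuse scatterer. The processed spectrum is
the decadic absorbance-like quantity

    A(lambda) = -log10( (sample - dark) / (reference - dark) )

cropped to the 450-650 nm working band. A geometry gate then requires
A(620 nm) to lie inside [0.5, 0.6]: the window corresponds to the intended
0.7 cm spot size and probe-to-nail distance, so values outside it indicate
the probe was held wrong and the acquisition should be repeated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import GateConfig
from .errors import CoverageError, SignalError, ValidationError
from .spectra_io import RawSpectrum, WavelengthGrid


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Processed (absorbance) spectrum on the working-band grid."""

    grid: WavelengthGrid
    absorbance: np.ndarray

    def __post_init__(self):
        absorbance = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", absorbance)
        if absorbance.shape != (len(self.grid),):
            raise ValidationError("absorbance length does not match grid length")
        if not np.all(np.isfinite(absorbance)):
            raise ValidationError("absorbance must be finite everywhere")

    def at(self, wavelength: float) -> float:
        """Absorbance at an arbitrary wavelength by linear interpolation."""
        if not self.grid.covers(wavelength):
            raise CoverageError(f"{wavelength} nm outside grid span {self.grid.span}")
        return float(np.interp(wavelength, self.grid.values, self.absorbance))


@dataclass(frozen=True)
class GateResult:
    """Outcome of the 620 nm amplitude gate."""

    absorbance_at_620: float
    lower: float
    upper: float
    passed: bool


def boxcar_smooth(spectrum: RawSpectrum, width: int) -> RawSpectrum:
    """Centered running average with a (2*width+1)-point window.

    Edge points use symmetrically truncated windows rather than padded data:
    the point at distance d < width from an edge averages 2d+1 points. Width
    0 returns the spectrum unchanged.
    """
    if width < 0:
        raise ValidationError("boxcar width must be non-negative")
    if width == 0:
        return spectrum
    n = len(spectrum.grid)
    if n <= 2 * width:
        raise ValidationError(
            f"spectrum of {n} points shorter than boxcar window {2 * width + 1}"
        )
    x = spectrum.intensities
    smoothed = np.empty_like(x)
    for i in range(n):
        half = min(width, i, n - 1 - i)
        smoothed[i] = x[i - half : i + half + 1].mean()
    return replace(spectrum, intensities=smoothed)


def compute_absorbance(
    sample: RawSpectrum,
    dark: RawSpectrum,
    reference: RawSpectrum,
    crop: tuple[float, float] = (450.0, 650.0),
) -> AbsorbanceSpectrum:
    """Dark-corrected decadic absorbance, cropped to the working band.

    Raises
    ------
    SignalError
        If ``reference - dark`` is anywhere non-positive (saturated or
        missing reference) or ``sample - dark`` is non-positive (the message
        names the offending wavelengths).
    """
    grids = {tuple(s.grid.values) for s in (sample, dark, reference)}
    if len(grids) != 1:
        raise ValidationError("sample, dark and reference must share one grid")
    wl = sample.grid.values

    ref_signal = reference.intensities - dark.intensities
    if np.any(ref_signal <= 0):
        bad = wl[ref_signal <= 0]
        raise SignalError(
            f"reference - dark non-positive at {bad.size} wavelengths "
            f"(first: {bad[:3].round(2).tolist()} nm); re-acquire reference"
        )
    sig = sample.intensities - dark.intensities
    if np.any(sig <= 0):
        bad = wl[sig <= 0]
        raise SignalError(
            f"sample - dark non-positive at {bad.size} wavelengths "
            f"(first: {bad[:3].round(2).tolist()} nm); re-acquire sample"
        )

    absorbance = -np.log10(sig / ref_signal)
    keep = (wl >= crop[0]) & (wl <= crop[1])
    if not keep.any():
        raise ValidationError(f"no grid points inside crop window {crop}")
    return AbsorbanceSpectrum(WavelengthGrid(wl[keep]), absorbance[keep])


def check_gate(spectrum: AbsorbanceSpectrum, gate: GateConfig | None = None) -> GateResult:
    """Evaluate the amplitude gate at the configured wavelength (620 nm).

    The absorbance at exactly 620 nm is linearly interpolated between the
    flanking grid points; the pass interval is inclusive at both ends.
    """
    gate = gate or GateConfig()
    a620 = spectrum.at(gate.wavelength_nm)
    return GateResult(
        absorbance_at_620=a620,
        lower=gate.lower,
        upper=gate.upper,
        passed=bool(gate.lower <= a620 <= gate.upper),
    )
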