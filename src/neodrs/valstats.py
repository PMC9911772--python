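"""Validation statistics: regression, Bland-Altman agreement, repeatability
and diagnostic sample-size estimation.

Conventions
-----------
* Differences are always oriented ``device - reference``.
* Limits of agreement use the conventional 1.96 multiplier on the SD of the
  differences.
* The standard deviation used for agreement and repeatability is the
  population form sqrt(sum((x_i - mu)**2) / N).
* Sample sizes use the Buderer equations for diagnostic tests:
  n_sens = z^2 * SN (1 - SN) / (W^2 * P), n_spec with SP and 1 - P, each
  rounded up to whole subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .spectra_io import PairedTable

LOA_MULTIPLIER = 1.96


def _population_sd(x: np.ndarray) -> float:
    """Population standard deviation sqrt(sum((x-mu)^2)/N)."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


@dataclass(frozen=True)
class RegressionReport:
    """Simple linear regression of device values on reference values."""

    r: float
    slope: float
    intercept: float
    n: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class BlandAltmanReport:
    """Agreement between device and reference: bias and 95% limits."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd": self.sd,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }


@dataclass(frozen=True)
class RepeatabilityReport:
    """Per-subject replicate means/SDs and the pooled SD (RMS of SDs)."""

    subject_means: tuple[float, ...]
    subject_sds: tuple[float, ...]
    pooled_sd: float
    k: int

    def to_dict(self) -> dict:
        return {
            "subject_means": list(self.subject_means),
            "subject_sds": list(self.subject_sds),
            "pooled_sd": self.pooled_sd,
            "k": self.k,
        }


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the diagnostic sample-size calculation.

    sensitivity/specificity/half-width/prevalence are fractions in (0, 1);
    z is the standard-normal quantile for the confidence level (1.96 = 95%).
    """

    sensitivity: float = 0.95
    specificity: float = 0.80
    half_width: float = 0.05
    prevalence: float = 0.15
    z: float = 1.96

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "half_width", "prevalence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.z <= 0:
            raise ValidationError("z must be positive")


def linear_regression(table: PairedTable) -> RegressionReport:
    """OLS of device on reference with Pearson r and two-sided slope p."""
    x, y = table.reference, table.device
    if x.size < 3:
        raise ValidationError("need at least 3 pairs for a regression p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant column: regression undefined")
    fit = stats.linregress(x, y)
    return RegressionReport(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
        p_value=float(fit.pvalue),
    )


def bland_altman(table: PairedTable) -> BlandAltmanReport:
    """Bias and 95% limits of agreement of device - reference differences."""
    diffs = table.device - table.reference
    if diffs.size < 2:
        raise ValidationError("need at least 2 pairs for agreement limits")
    bias = float(diffs.mean())
    sd = _population_sd(diffs)
    return BlandAltmanReport(
        bias=bias,
        sd=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n=int(diffs.size),
    )


def repeatability(replicates: dict[str, "np.ndarray | list[float]"]) -> RepeatabilityReport:
    """Within-subject repeatability over k back-to-back measurements.

    Each subject's mean is the plain arithmetic mean and its SD the
    population SD of the replicates; the pooled SD is the root mean square
    of the per-subject SDs.
    """
    if not replicates:
        raise ValidationError("no subjects supplied")
    means, sds, ks = [], [], []
    for subject, values in replicates.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValidationError(f"subject {subject!r} has fewer than 2 replicates")
        means.append(float(values.mean()))
        sds.append(_population_sd(values))
        ks.append(values.size)
    pooled = float(np.sqrt(np.mean(np.square(sds))))
    return RepeatabilityReport(
        subject_means=tuple(means),
        subject_sds=tuple(sds),
        pooled_sd=pooled,
        k=min(ks),
    )


def sample_size(spec: SampleSizeSpec) -> tuple[int, int]:
    """Minimum subjects to bound sensitivity and specificity CIs.

    Returns ``(n_sensitivity, n_specificity)`` where::

        n_sensitivity = ceil( z^2 * SN (1-SN) / (W^2 * P) )
        n_specificity = ceil( z^2 * SP (1-SP) / (W^2 * (1-P)) )

    With SN=0.95, SP=0.80, W=0.05, P=0.15, z=1.96 this gives (487, 290).
    """
    z2 = spec.z**2
    w2 = spec.half_width**2
    n_sens = z2 * spec.sensitivity * (1 - spec.sensitivity) / (w2 * spec.prevalence)
    n_spec = z2 * spec.specificity * (1 - spec.specificity) / (w2 * (1 - spec.prevalence))
    return math.ceil(n_sens), math.ceil(n_spec)
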