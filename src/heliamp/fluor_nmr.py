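"""Tryptophan-environment readouts: emission maxima and Ha secondary shifts.

The emission maximum is taken as the argmax of a centered moving-average
smoothed intensity (default 5 points; instrument traces are recorded on fine
grids and the raw argmax is noise-sensitive).  Delta-lambda-max is the signed
difference peptide minus reference; negative values are blue shifts.
Secondary 1Ha chemical shifts are deviations from a random-coil reference
(4.7 ppm for Trp); a sustained upfield deviation of at least 0.1 ppm flags a
helical tendency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "FluorSummary",
    "NmrShift",
    "lambda_max",
    "delta_lambda_max",
    "secondary_shift",
    "TRP_RANDOM_COIL_HA",
    "HELICAL_SHIFT_THRESHOLD",
]

TRP_RANDOM_COIL_HA = 4.7       # ppm
HELICAL_SHIFT_THRESHOLD = -0.1  # ppm; secondary shift at or below this flags helix


@dataclass(frozen=True)
class EmissionSpectrum:
    """Fluorescence emission trace on a strictly ascending wavelength grid."""

    wavelengths: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.wavelengths.shape != self.intensity.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelength and intensity arrays must be 1-D and aligned")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")


@dataclass(frozen=True)
class FluorSummary:
    label: str
    lambda_max: float
    delta_lambda_max: float | None = None


@dataclass(frozen=True)
class NmrShift:
    residue_label: str
    delta_ha: float
    reference_rc: float
    secondary_shift: float
    helical_flag: bool


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    # centered window, shrunk symmetrically at the edges
    half = window // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def lambda_max(spectrum: EmissionSpectrum, smooth_window: int = 5) -> float:
    """Wavelength of the smoothed intensity maximum; ties break low."""
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if len(spectrum.wavelengths) < smooth_window:
        raise ValueError(
            f"spectrum has {len(spectrum.wavelengths)} points, "
            f"fewer than smooth_window={smooth_window}"
        )
    smoothed = _moving_average(spectrum.intensity, smooth_window)
    return float(spectrum.wavelengths[int(np.argmax(smoothed))])


def delta_lambda_max(
    peptide_spectrum: EmissionSpectrum,
    reference_spectrum: EmissionSpectrum,
    smooth_window: int = 5,
) -> float:
    """Signed lambda_max difference, peptide minus reference (negative = blue shift)."""
    return lambda_max(peptide_spectrum, smooth_window) - lambda_max(
        reference_spectrum, smooth_window
    )


def secondary_shift(
    delta_ha: float,
    reference_rc: float = TRP_RANDOM_COIL_HA,
    residue_label: str = "W",
) -> NmrShift:
    """Secondary 1Ha shift and the helical-tendency flag (<= -0.1 ppm)."""
    if not 2.0 <= delta_ha <= 6.0:
        warnings.warn(
            f"delta_ha {delta_ha} ppm outside the plausible 2-6 ppm range",
            stacklevel=2,
        )
    shift = delta_ha - reference_rc
    return NmrShift(
        residue_label=residue_label,
        delta_ha=delta_ha,
        reference_rc=reference_rc,
        secondary_shift=shift,
        helical_flag=shift <= HELICAL_SHIFT_THRESHOLD,
    )
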