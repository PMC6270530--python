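"""Circular dichroism normalization and helicity parameters.

Raw machine signal (mdeg) is converted to mean residue molar ellipticity

    [theta]_lambda = theta_mdeg / (10 * C_molar * l_cm * N_residues)

in deg cm^2 dmol^-1.  Helical fraction uses a single-wavelength two-state
estimator at 222 nm with documented constants (coil baseline +640,
infinite-helix limit -42500 with a 3-residue end correction), clipped to
[0, 1].  The isodichroic point of a spectral family is the wavelength of
minimal across-spectra dispersion within a window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SpectrumMetadata",
    "RawSpectrum",
    "CDSpectrum",
    "CDSummary",
    "normalize_ellipticity",
    "denormalize_ellipticity",
    "value_at",
    "helical_fraction",
    "theta_product",
    "isodichroic_point",
    "resample",
    "summarize_cd",
    "THETA_COIL_222",
    "THETA_HELIX_INF",
    "HELIX_END_CORRECTION",
]

THETA_COIL_222 = 640.0       # deg cm^2 dmol^-1, coil baseline at 222 nm
THETA_HELIX_INF = -42500.0   # infinite-helix limit at 222 nm
HELIX_END_CORRECTION = 3.0   # k in (1 - k/n)


@dataclass(frozen=True)
class SpectrumMetadata:
    concentration_molar: float
    path_cm: float
    n_residues: int
    solvent: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.concentration_molar <= 0 or self.path_cm <= 0 or self.n_residues <= 0:
            raise ValueError("concentration, path length and residue count must be positive")


def _check_grid(wavelengths: np.ndarray, signal: np.ndarray) -> None:
    if wavelengths.shape != signal.shape or wavelengths.ndim != 1:
        raise ValueError("wavelength and signal arrays must be 1-D and aligned")
    diffs = np.diff(wavelengths)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("wavelength grid must be strictly monotone")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")


@dataclass(frozen=True)
class RawSpectrum:
    """Machine signal in mdeg on a monotone wavelength grid."""

    wavelengths: np.ndarray
    signal_mdeg: np.ndarray
    metadata: SpectrumMetadata

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "signal_mdeg", np.asarray(self.signal_mdeg, dtype=float))
        _check_grid(self.wavelengths, self.signal_mdeg)


@dataclass(frozen=True)
class CDSpectrum:
    """Mean residue molar ellipticity, deg cm^2 dmol^-1."""

    wavelengths: np.ndarray
    theta: np.ndarray
    metadata: SpectrumMetadata

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        _check_grid(self.wavelengths, self.theta)


@dataclass(frozen=True)
class CDSummary:
    theta_222: float
    theta_208: float
    theta_203: float
    theta_product: float
    helical_fraction: float


def normalize_ellipticity(raw: RawSpectrum, blank: RawSpectrum | None = None) -> CDSpectrum:
    """mdeg -> mean residue molar ellipticity; optional blank subtraction first."""
    signal = raw.signal_mdeg
    if blank is not None:
        if not np.array_equal(blank.wavelengths, raw.wavelengths):
            raise ValueError("blank spectrum must share the sample wavelength grid")
        signal = signal - blank.signal_mdeg
    md = raw.metadata
    factor = 10.0 * md.concentration_molar * md.path_cm * md.n_residues
    return CDSpectrum(wavelengths=raw.wavelengths.copy(), theta=signal / factor, metadata=md)


def denormalize_ellipticity(spectrum: CDSpectrum) -> RawSpectrum:
    """Inverse of :func:`normalize_ellipticity` (exact round trip)."""
    md = spectrum.metadata
    factor = 10.0 * md.concentration_molar * md.path_cm * md.n_residues
    return RawSpectrum(
        wavelengths=spectrum.wavelengths.copy(),
        signal_mdeg=spectrum.theta * factor,
        metadata=md,
    )


def value_at(spectrum: CDSpectrum, wavelength: float) -> float:
    """Linear interpolation on the grid; exact at grid points."""
    wl = spectrum.wavelengths
    theta = spectrum.theta
    if wl[0] > wl[-1]:
        wl, theta = wl[::-1], theta[::-1]
    if not wl[0] <= wavelength <= wl[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside grid range [{wl[0]}, {wl[-1]}]"
        )
    return float(np.interp(wavelength, wl, theta))


def helical_fraction(theta_222: float, n_residues: int) -> float:
    """Two-state single-wavelength helicity estimate, clipped to [0, 1]."""
    if n_residues < 4:
        raise ValueError("estimator requires at least 4 residues")
    theta_helix = THETA_HELIX_INF * (1.0 - HELIX_END_CORRECTION / n_residues)
    fraction = (theta_222 - THETA_COIL_222) / (theta_helix - THETA_COIL_222)
    return float(np.clip(fraction, 0.0, 1.0))


def theta_product(theta_222: float, theta_208: float) -> float:
    """Plain product [theta]222 x [theta]208, sign preserved."""
    return theta_222 * theta_208


def resample(spectrum: CDSpectrum, step: float = 0.5) -> CDSpectrum:
    """Linear resampling onto a uniform grid at ``step`` nm (ascending)."""
    wl = spectrum.wavelengths
    theta = spectrum.theta
    if wl[0] > wl[-1]:
        wl, theta = wl[::-1], theta[::-1]
    grid = np.arange(np.ceil(wl[0] / step) * step, wl[-1] + step / 2, step)
    grid = grid[(grid >= wl[0]) & (grid <= wl[-1])]
    return CDSpectrum(
        wavelengths=grid, theta=np.interp(grid, wl, theta), metadata=spectrum.metadata
    )


def isodichroic_point(
    spectra: list[CDSpectrum],
    window: tuple[float, float] = (195.0, 215.0),
    step: float = 0.5,
    tolerance_frac: float = 0.10,
) -> float | None:
    """Wavelength of minimal across-spectra standard deviation of [theta].

    All spectra are resampled to a common ``step``-nm grid restricted to
    ``window``.  Returns ``None`` when the minimal deviation exceeds
    ``tolerance_frac`` of the median |[theta]| there (no credible crossing).
    Ties break to the lowest wavelength.
    """
    if len(spectra) < 3:
        raise ValueError("need at least 3 spectra to locate an isodichroic point")
    resampled = [resample(s, step) for s in spectra]
    lo = max(s.wavelengths[0] for s in resampled)
    hi = min(s.wavelengths[-1] for s in resampled)
    lo, hi = max(lo, window[0]), min(hi, window[1])
    if lo >= hi:
        raise ValueError("spectra do not share a common grid over the window")
    grid = np.arange(np.ceil(lo / step) * step, hi + step / 2, step)
    matrix = np.vstack(
        [np.interp(grid, s.wavelengths, s.theta) for s in resampled]
    )
    deviation = matrix.std(axis=0)
    # lowest wavelength among near-ties (std of identical rows is not exactly 0
    # in floating point)
    eps = 1e-9 * max(1.0, float(np.abs(matrix).max()))
    idx = int(np.argmax(deviation <= deviation.min() + eps))
    scale = float(np.median(np.abs(matrix[:, idx])))
    if scale > 0 and deviation[idx] > tolerance_frac * scale:
        return None
    return float(grid[idx])


def summarize_cd(spectrum: CDSpectrum) -> CDSummary:
    """Extract the standard wavelength readouts and the helicity estimate."""
    t222 = value_at(spectrum, 222.0)
    t208 = value_at(spectrum, 208.0)
    t203 = value_at(spectrum, 203.0)
    return CDSummary(
        theta_222=t222,
        theta_208=t208,
        theta_203=t203,
        theta_product=theta_product(t222, t208),
        helical_fraction=helical_fraction(t222, spectrum.metadata.n_residues),
    )
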