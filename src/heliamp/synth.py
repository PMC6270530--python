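"""Seeded synthetic-data generators for every input kind the analyses consume.

All randomness flows from the explicit seed in :class:`SynthConfig`; there is
no global random state.  The CD generator mixes a helix and a coil Gaussian-
band basis (a testability device, not band theory): the helix basis is scaled
so its 222 nm value equals the finite-length helix limit used by the
estimator in :mod:`heliamp.cd`, and the coil basis is offset so its 222 nm
value equals the coil baseline.  A noiseless synthetic spectrum therefore
round-trips through normalization and the helicity estimator exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from heliamp.activity import Bound, HemolysisCurve, MICTable
from heliamp.cd import (
    HELIX_END_CORRECTION,
    THETA_COIL_222,
    THETA_HELIX_INF,
    RawSpectrum,
    SpectrumMetadata,
)
from heliamp.fluor_nmr import EmissionSpectrum

__all__ = [
    "SynthConfig",
    "helix_basis",
    "coil_basis",
    "synth_cd",
    "synth_emission",
    "synth_hemolysis",
    "synth_mic_table",
    "synth_sar_table",
    "TWOFOLD_SERIES",
]

TWOFOLD_SERIES = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)

# (center nm, sigma nm, nominal amplitude) Gaussian bands
HELIX_BANDS = ((193.0, 5.5, 75000.0), (208.0, 5.0, -33000.0), (222.0, 6.0, -35000.0))
COIL_BAND = (198.0, 7.0, -40000.0)


@dataclass
class SynthConfig:
    seed: int
    n_peptides: int = 11
    n_residues: int = 11
    cd_noise_sd: float = 0.0            # deg cm^2 dmol^-1
    cd_concentration_molar: float = 45e-6
    cd_path_cm: float = 0.2
    fluor_noise_frac: float = 0.0       # fraction of peak intensity
    hemolysis_hill_coefficient: float = 3.0
    hemolysis_hc50_range: tuple[float, float] = (16.0, 256.0)
    mic_log2_mean: float = 1.5
    mic_log2_sd: float = 1.0
    planted_sar_slope: float = 80.0
    planted_sar_intercept: float = 5.0
    sar_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("cd_noise_sd", "fluor_noise_frac", "mic_log2_sd", "sar_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator per named stream, all derived from the seed."""
        # crc32 is stable across processes (str hash is salted)
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


def _gauss(wavelengths: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((wavelengths - center) ** 2) / (2.0 * sigma**2))


def helix_basis(wavelengths: np.ndarray, n_residues: int) -> np.ndarray:
    """Helix basis spectrum pinned to the finite-length limit at 222 nm."""
    raw = sum(a * _gauss(wavelengths, c, s) for c, s, a in HELIX_BANDS)
    raw_222 = sum(a * _gauss(np.array([222.0]), c, s)[0] for c, s, a in HELIX_BANDS)
    target_222 = THETA_HELIX_INF * (1.0 - HELIX_END_CORRECTION / n_residues)
    return raw * (target_222 / raw_222)


def coil_basis(wavelengths: np.ndarray) -> np.ndarray:
    """Coil basis spectrum offset to the coil baseline at 222 nm."""
    c, s, a = COIL_BAND
    band = a * _gauss(wavelengths, c, s)
    band_222 = a * _gauss(np.array([222.0]), c, s)[0]
    return band + (THETA_COIL_222 - band_222)


def synth_cd(
    f_helix: float,
    config: SynthConfig,
    label: str = "",
    wavelength_range: tuple[float, float] = (190.0, 260.0),
    step: float = 0.5,
) -> RawSpectrum:
    """Two-state mixture spectrum, returned in machine units (mdeg)."""
    if not 0.0 <= f_helix <= 1.0:
        raise ValueError(f"f_helix must be in [0, 1], got {f_helix}")
    wavelengths = np.arange(wavelength_range[0], wavelength_range[1] + step / 2, step)
    theta = f_helix * helix_basis(wavelengths, config.n_residues) + (
        1.0 - f_helix
    ) * coil_basis(wavelengths)
    if config.cd_noise_sd > 0:
        theta = theta + config.rng(f"cd:{label}:{f_helix}").normal(
            0.0, config.cd_noise_sd, size=wavelengths.shape
        )
    metadata = SpectrumMetadata(
        concentration_molar=config.cd_concentration_molar,
        path_cm=config.cd_path_cm,
        n_residues=config.n_residues,
        label=label,
    )
    factor = 10.0 * metadata.concentration_molar * metadata.path_cm * metadata.n_residues
    return RawSpectrum(wavelengths=wavelengths, signal_mdeg=theta * factor, metadata=metadata)


def synth_emission(
    lambda_max_true: float,
    config: SynthConfig,
    label: str = "",
    sigma_blue: float = 18.0,
    sigma_red: float = 25.0,
    step: float = 0.2,
) -> EmissionSpectrum:
    """Asymmetric-Gaussian emission peak; the noiseless mode is lambda_max_true."""
    if not 300.0 < lambda_max_true < 450.0:
        raise ValueError(f"lambda_max_true must lie in (300, 450), got {lambda_max_true}")
    wavelengths = np.arange(300.0, 450.0 + step / 2, step)
    sigma = np.where(wavelengths < lambda_max_true, sigma_blue, sigma_red)
    intensity = np.exp(-((wavelengths - lambda_max_true) ** 2) / (2.0 * sigma**2))
    if config.fluor_noise_frac > 0:
        noise = config.rng(f"fluor:{label}:{lambda_max_true}").normal(
            0.0, config.fluor_noise_frac, size=wavelengths.shape
        )
        intensity = np.clip(intensity * (1.0 + noise), 0.0, None)
    return EmissionSpectrum(wavelengths=wavelengths, intensity=intensity, label=label)


def synth_hemolysis(
    hc50: float,
    hill: float,
    series: tuple[float, ...] = TWOFOLD_SERIES,
    peptide_id: str = "synthetic",
) -> HemolysisCurve:
    """Hill dose-response H(c) = 100 / (1 + (hc50/c)^hill) on a dilution series."""
    if hc50 <= 0 or hill <= 0:
        raise ValueError("hc50 and hill must be positive")
    concentrations = list(series)
    percent = [100.0 / (1.0 + (hc50 / c) ** hill) for c in concentrations]
    return HemolysisCurve(
        peptide_id=peptide_id,
        concentrations=concentrations,
        hemolysis_percent=percent,
    )


def synth_mic_table(
    config: SynthConfig,
    n_gram_positive: int = 4,
    n_gram_negative: int = 5,
    n_other: int = 1,
) -> MICTable:
    """Two-fold-quantized MIC table: per-cell lognormal potency rounded up
    to the next power of two, clipped to [1, 128]."""
    rng = config.rng("mic")
    peptide_ids = [f"W{i}" for i in range(1, config.n_peptides + 1)]
    strain_ids = (
        [f"GP{i}" for i in range(1, n_gram_positive + 1)]
        + [f"GN{i}" for i in range(1, n_gram_negative + 1)]
        + [f"OT{i}" for i in range(1, n_other + 1)]
    )
    gram_labels = (
        ["positive"] * n_gram_positive + ["negative"] * n_gram_negative + ["other"] * n_other
    )
    mic: dict[tuple[str, str], float | Bound] = {}
    for pid in peptide_ids:
        for sid in strain_ids:
            log2_potency = rng.normal(config.mic_log2_mean, config.mic_log2_sd)
            value = 2.0 ** np.ceil(log2_potency)
            mic[(pid, sid)] = float(np.clip(value, 1.0, 128.0))
    return MICTable(
        peptide_ids=peptide_ids, strain_ids=strain_ids, gram_labels=gram_labels, mic=mic
    )


def synth_sar_table(config: SynthConfig):
    """Planted linear relation: hemolysis % = slope * f_helix + intercept + noise.

    Returns a :class:`heliamp.sar.SarTable` with an ``f_helix`` parameter
    column; used for end-to-end parameter-recovery tests.
    """
    import pandas as pd

    from heliamp.sar import SarTable

    rng = config.rng("sar")
    peptide_ids = [f"W{i}" for i in range(1, config.n_peptides + 1)]
    f_helix = rng.uniform(0.3, 1.0, size=config.n_peptides)
    noise = (
        rng.normal(0.0, config.sar_noise_sd, size=config.n_peptides)
        if config.sar_noise_sd > 0
        else np.zeros(config.n_peptides)
    )
    hemolysis = config.planted_sar_slope * f_helix + config.planted_sar_intercept + noise
    return SarTable(
        peptide_ids=peptide_ids,
        activity=hemolysis,
        parameters=pd.DataFrame({"f_helix": f_helix}),
    )
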