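"""Sequence-level physicochemical descriptors.

Mean residue hydrophobicity and the helical hydrophobic moment are computed
against pluggable named scales (the Eisenberg consensus scale ships as a
packaged resource).  Masses are average isotopic by default so that amidated
undecapeptide masses round to the values quoted for synthesized material;
monoisotopic masses are available behind a flag.  The charge model is plain
integer counting at neutral pH (+1 per Lys/Arg side chain, +1 for the free
N-terminal amine, -1 for a free C-terminal carboxylate), with no pKa
titration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from heliamp.design import DesignedPeptide

__all__ = [
    "HydrophobicityScale",
    "PhyschemProfile",
    "load_scale",
    "mean_hydrophobicity",
    "hydrophobic_moment",
    "polar_angle",
    "molecular_mass",
    "net_charge",
    "concentration_from_absorbance",
    "physchem_profile",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# average isotopic residue (i.e. dehydrated) masses, Da
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
MONOISOTOPIC_RESIDUE_MASS = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694, "C": 103.00919,
    "E": 129.04259, "Q": 128.05858, "G": 57.02146, "H": 137.05891, "I": 113.08406,
    "L": 113.08406, "K": 128.09496, "M": 131.04049, "F": 147.06841, "P": 97.05276,
    "S": 87.03203, "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}
WATER_AVERAGE = 18.01524
WATER_MONO = 18.010565
# C-terminal amide: -OH +NH2
AMIDE_CORRECTION_AVERAGE = -17.00734 + 16.02258
AMIDE_CORRECTION_MONO = -17.00274 + 16.01872

TRP_MOLAR_ABSORPTIVITY_280 = 5500.0  # M^-1 cm^-1


@dataclass(frozen=True)
class HydrophobicityScale:
    """Named per-residue hydrophobicity table (dimensionless)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = sorted(set(STANDARD_RESIDUES) - set(self.values))
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {''.join(missing)}")
        bad = [r for r, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"scale {self.name!r} has non-finite values for {bad}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


@dataclass(frozen=True)
class PhyschemProfile:
    """Descriptor bundle for one peptide."""

    peptide_id: str
    sequence: str
    length: int
    mean_hydrophobicity: float
    hydrophobic_moment: float
    polar_angle: float
    molecular_mass: float
    net_charge: int
    scale_name: str


def load_scale(name_or_path: str = "eisenberg-consensus") -> HydrophobicityScale:
    """Load a scale by packaged name or from a two-column text file.

    File format: one ``<one-letter code> <value>`` pair per line; ``#`` starts
    a comment.
    """
    path = Path(name_or_path)
    if path.exists():
        text = path.read_text()
        name = path.stem
    else:
        resource = resources.files("heliamp.data") / f"{name_or_path.replace('-', '_')}.txt"
        try:
            text = resource.read_text()
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no packaged scale or file named {name_or_path!r}"
            ) from None
        name = name_or_path
    values: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{name}: malformed scale line {lineno}: {line!r}")
        values[parts[0].upper()] = float(parts[1])
    return HydrophobicityScale(name=name, values=values)


def _check_sequence(sequence: str, scale: HydrophobicityScale) -> None:
    for i, residue in enumerate(sequence, start=1):
        if residue not in scale.values:
            raise ValueError(f"unknown residue {residue!r} at position {i}")


def mean_hydrophobicity(sequence: str, scale: HydrophobicityScale) -> float:
    """Arithmetic mean of per-residue scale values."""
    if not sequence:
        raise ValueError("empty sequence")
    _check_sequence(sequence, scale)
    return sum(scale[r] for r in sequence) / len(sequence)


def hydrophobic_moment(
    sequence: str, scale: HydrophobicityScale, delta: float = 100.0
) -> float:
    """Helical hydrophobic moment per residue.

    muH = (1/N) * |sum_i h_i * exp(j * delta * (i - 1))| with residue i
    contributing at angle delta*(i-1); the magnitude is phase-invariant.
    """
    if not sequence:
        raise ValueError("empty sequence")
    _check_sequence(sequence, scale)
    sin_sum = 0.0
    cos_sum = 0.0
    for i, residue in enumerate(sequence):
        angle = math.radians(delta * i)
        h = scale[residue]
        sin_sum += h * math.sin(angle)
        cos_sum += h * math.cos(angle)
    return math.hypot(sin_sum, cos_sum) / len(sequence)


def polar_angle(peptide: DesignedPeptide) -> float:
    """Angular span of the cationic face on the helical wheel.

    Circular distance from the clockwise-most to the counterclockwise-most
    cationic residue angle; requires a perfectly amphipathic peptide.
    """
    from heliamp.design import validate_amphipathic

    ok, diagnostic = validate_amphipathic(peptide)
    if not ok:
        raise ValueError(f"polar angle undefined for non-amphipathic peptide: {diagnostic}")
    angles = sorted(
        peptide.wheel.angle_of(i + 1)
        for i, r in enumerate(peptide.sequence)
        if r == peptide.formula.cationic_residue
    )
    # the arc is the complement of the largest gap between consecutive angles
    gaps = [
        (angles[(i + 1) % len(angles)] - angles[i]) % 360.0 for i in range(len(angles))
    ]
    return 360.0 - max(gaps)


def molecular_mass(
    sequence: str, c_terminal_amide: bool = True, monoisotopic: bool = False
) -> float:
    """Peptide mass in Da (average isotopic unless ``monoisotopic``)."""
    if not sequence:
        raise ValueError("empty sequence")
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    water = WATER_MONO if monoisotopic else WATER_AVERAGE
    amide = AMIDE_CORRECTION_MONO if monoisotopic else AMIDE_CORRECTION_AVERAGE
    total = water
    for i, residue in enumerate(sequence, start=1):
        try:
            total += table[residue]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r} at position {i}") from None
    if c_terminal_amide:
        total += amide
    return total


def net_charge(sequence: str, c_terminal_amide: bool = True) -> int:
    """Integer net charge at neutral pH: +1 per K/R, +1 N-terminus, -1 free C-terminus."""
    charge = 1  # free N-terminal amine
    charge += sum(1 for r in sequence if r in "KR")
    if not c_terminal_amide:
        charge -= 1
    return charge


def concentration_from_absorbance(a280: float, path_cm: float, n_trp: int) -> float:
    """Molar concentration from A280 via the Trp molar absorptivity (5500 M^-1 cm^-1)."""
    if a280 < 0:
        raise ValueError("absorbance must be >= 0")
    if n_trp < 1:
        raise ValueError("method requires at least one tryptophan")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    return a280 / (TRP_MOLAR_ABSORPTIVITY_280 * n_trp * path_cm)


def physchem_profile(
    peptide: DesignedPeptide, scale: HydrophobicityScale
) -> PhyschemProfile:
    """Assemble the full descriptor bundle for one designed peptide."""
    return PhyschemProfile(
        peptide_id=peptide.peptide_id,
        sequence=peptide.sequence,
        length=len(peptide.sequence),
        mean_hydrophobicity=mean_hydrophobicity(peptide.sequence, scale),
        hydrophobic_moment=hydrophobic_moment(
            peptide.sequence, scale, peptide.wheel.residues_per_turn_angle
        ),
        polar_angle=polar_angle(peptide),
        molecular_mass=molecular_mass(peptide.sequence, peptide.c_terminal_amide),
        net_charge=net_charge(peptide.sequence, peptide.c_terminal_amide),
        scale_name=scale.name,
    )
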