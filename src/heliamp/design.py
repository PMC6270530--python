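"""Helical-wheel peptide design: perfectly amphipathic isomer families.

A peptide built from m copies of a hydrophobic residue, m copies of a
cationic residue and one interface residue (total length n = 2m + 1) is
"perfectly amphipathic" when, projected onto the helical wheel, the cationic
residues occupy one contiguous angular arc, the hydrophobic residues the
complementary arc, and the interface residue sits between the end of the
cationic arc and the start of the hydrophobic arc.

The wheel places 1-based sequence position i at angle ((i - 1) * delta) mod
360 with delta = 100 degrees for an ideal alpha-helix, angles increasing
counterclockwise viewed from the N-terminus.  For a given interface position
the hydrophobic residues are assigned to the m remaining positions nearest
counterclockwise (increasing angle) of the interface residue and the cationic
residues to the m nearest clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GeometryError",
    "WheelGeometry",
    "PeptideFormula",
    "DesignedPeptide",
    "wheel_angles",
    "design_isomer",
    "enumerate_family",
    "validate_amphipathic",
    "check_sequence_amphipathic",
]

DEFAULT_DELTA = 100.0


class GeometryError(ValueError):
    """Raised when the wheel geometry leaves the partition rule undefined."""


@dataclass(frozen=True)
class WheelGeometry:
    """Angular positions of residues on an ideal helical wheel.

    ``angles[i - 1]`` is the angle (degrees in [0, 360)) of 1-based sequence
    position ``i``.
    """

    residues_per_turn_angle: float
    n_residues: int
    angles: tuple[float, ...]

    def angle_of(self, position: int) -> float:
        """Angle of a 1-based sequence position."""
        if not 1 <= position <= self.n_residues:
            raise ValueError(f"position {position} outside [1, {self.n_residues}]")
        return self.angles[position - 1]

    @property
    def has_distinct_angles(self) -> bool:
        return len(set(self.angles)) == self.n_residues


@dataclass(frozen=True)
class PeptideFormula:
    """Residue composition of a perfectly amphipathic design.

    hydrophobic_count must equal cationic_count; total length is
    2 * hydrophobic_count + 1 (one interface residue).
    """

    hydrophobic_residue: str = "L"
    cationic_residue: str = "K"
    interface_residue: str = "W"
    hydrophobic_count: int = 5
    cationic_count: int = 5

    def __post_init__(self) -> None:
        for name in ("hydrophobic_residue", "cationic_residue", "interface_residue"):
            letter = getattr(self, name)
            if len(letter) != 1 or not letter.isalpha():
                raise ValueError(f"{name} must be a single letter, got {letter!r}")
        if self.hydrophobic_count != self.cationic_count:
            raise ValueError(
                "perfect amphipathy requires hydrophobic_count == cationic_count "
                f"(got {self.hydrophobic_count} != {self.cationic_count})"
            )
        if self.hydrophobic_count < 1:
            raise ValueError("counts must be >= 1")
        if len({self.hydrophobic_residue, self.cationic_residue, self.interface_residue}) != 3:
            raise ValueError("the three residue letters must be distinct")

    @property
    def length(self) -> int:
        return 2 * self.hydrophobic_count + 1

    @property
    def name(self) -> str:
        m = self.hydrophobic_count
        return f"{self.hydrophobic_residue}{m}{self.cationic_residue}{m}{self.interface_residue}"


@dataclass(frozen=True)
class DesignedPeptide:
    """A designed isomer: sequence plus its wheel geometry and metadata."""

    sequence: str
    trp_position: int
    formula: PeptideFormula
    wheel: WheelGeometry
    c_terminal_amide: bool = True
    peptide_id: str = field(default="")

    def __post_init__(self) -> None:
        if len(self.sequence) != self.wheel.n_residues:
            raise ValueError("sequence length does not match wheel geometry")
        if self.sequence[self.trp_position - 1] != self.formula.interface_residue:
            raise ValueError(
                f"position {self.trp_position} is {self.sequence[self.trp_position - 1]}, "
                f"expected interface residue {self.formula.interface_residue}"
            )
        if not self.peptide_id:
            object.__setattr__(self, "peptide_id", f"W{self.trp_position}")


def wheel_angles(n: int, delta: float = DEFAULT_DELTA) -> WheelGeometry:
    """Build the wheel geometry for ``n`` residues at ``delta`` degrees/residue.

    Raises :class:`GeometryError` when two positions land on the same angle,
    because the arc-partition rule is then undefined.
    """
    if n < 2:
        raise ValueError(f"need at least 2 residues, got {n}")
    if not 0.0 < delta < 360.0:
        raise ValueError(f"delta must be in (0, 360), got {delta}")
    angles = tuple(((i - 1) * delta) % 360.0 for i in range(1, n + 1))
    geometry = WheelGeometry(residues_per_turn_angle=delta, n_residues=n, angles=angles)
    if not geometry.has_distinct_angles:
        raise GeometryError(
            f"duplicate wheel angles for n={n}, delta={delta}: partition rule undefined"
        )
    return geometry


def _ccw_distance(from_angle: float, to_angle: float) -> float:
    """Counterclockwise (increasing-angle) distance from one angle to another."""
    return (to_angle - from_angle) % 360.0


def design_isomer(
    formula: PeptideFormula,
    trp_position: int,
    geometry: WheelGeometry | None = None,
    c_terminal_amide: bool = True,
) -> DesignedPeptide:
    """Place the interface residue and partition the wheel around it.

    Of the 2m non-interface positions, the m whose wheel angles are nearest
    the interface angle going counterclockwise receive the hydrophobic
    residue; the m nearest going clockwise receive the cationic residue.
    """
    if geometry is None:
        geometry = wheel_angles(formula.length)
    if geometry.n_residues != formula.length:
        raise ValueError(
            f"geometry has {geometry.n_residues} positions but formula requires {formula.length}"
        )
    if not geometry.has_distinct_angles:
        raise GeometryError("duplicate wheel angles: partition rule undefined")
    n = formula.length
    if not 1 <= trp_position <= n:
        raise ValueError(f"trp_position {trp_position} outside [1, {n}]")

    w_angle = geometry.angle_of(trp_position)
    others = [p for p in range(1, n + 1) if p != trp_position]
    # ascending ccw distance from the interface angle: first m -> hydrophobic
    others.sort(key=lambda p: _ccw_distance(w_angle, geometry.angle_of(p)))
    m = formula.hydrophobic_count
    residues = [""] * n
    residues[trp_position - 1] = formula.interface_residue
    for p in others[:m]:
        residues[p - 1] = formula.hydrophobic_residue
    for p in others[m:]:
        residues[p - 1] = formula.cationic_residue
    peptide = DesignedPeptide(
        sequence="".join(residues),
        trp_position=trp_position,
        formula=formula,
        wheel=geometry,
        c_terminal_amide=c_terminal_amide,
    )
    ok, diagnostic = validate_amphipathic(peptide)
    if not ok:  # pragma: no cover - construction guarantees validity
        raise GeometryError(f"constructed isomer failed validation: {diagnostic}")
    return peptide


def enumerate_family(
    formula: PeptideFormula,
    geometry: WheelGeometry | None = None,
    c_terminal_amide: bool = True,
) -> list[DesignedPeptide]:
    """One designed isomer per interface position 1..n."""
    if geometry is None:
        geometry = wheel_angles(formula.length)
    family = [
        design_isomer(formula, pos, geometry, c_terminal_amide=c_terminal_amide)
        for pos in range(1, formula.length + 1)
    ]
    sequences = [p.sequence for p in family]
    if len(set(sequences)) != len(sequences):  # pragma: no cover
        raise GeometryError("enumeration produced duplicate sequences")
    return family


def _is_contiguous_arc(member_angles: list[float], all_angles: list[float]) -> bool:
    """True if the members occupy consecutive slots of the circular angle order."""
    order = sorted(all_angles)
    n = len(order)
    member = set(member_angles)
    flags = [a in member for a in order]
    # count blocks of True on the circle
    transitions = sum(
        1 for i in range(n) if flags[i] and not flags[(i - 1) % n]
    )
    return transitions == 1


def validate_amphipathic(peptide: DesignedPeptide) -> tuple[bool, str]:
    """Check perfect amphipathy of a designed peptide; returns (ok, diagnostic)."""
    return check_sequence_amphipathic(peptide.sequence, peptide.formula, peptide.wheel)


def check_sequence_amphipathic(
    seq: str, formula: PeptideFormula, geometry: WheelGeometry
) -> tuple[bool, str]:
    """Check perfect amphipathy of an arbitrary sequence; returns (ok, diagnostic).

    Conditions, tested in order:
      (a) composition matches the formula;
      (b) cationic angles form one contiguous circular arc;
      (c) hydrophobic angles form the complementary contiguous arc;
      (d) the interface angle lies strictly between the counterclockwise end
          of the cationic arc and the clockwise start of the hydrophobic arc.
    """
    if len(seq) != geometry.n_residues:
        return False, "sequence length does not match wheel geometry"
    counts = {
        formula.hydrophobic_residue: formula.hydrophobic_count,
        formula.cationic_residue: formula.cationic_count,
        formula.interface_residue: 1,
    }
    for letter, expected in counts.items():
        if seq.count(letter) != expected:
            return False, (
                f"composition mismatch: expected {expected} x {letter}, "
                f"found {seq.count(letter)}"
            )
    if len(seq) != sum(counts.values()):
        return False, "composition mismatch: unexpected residues present"

    all_angles = list(geometry.angles)
    cationic = [geometry.angle_of(i + 1) for i, r in enumerate(seq) if r == formula.cationic_residue]
    hydrophobic = [
        geometry.angle_of(i + 1) for i, r in enumerate(seq) if r == formula.hydrophobic_residue
    ]
    w_angle = geometry.angle_of(seq.index(formula.interface_residue) + 1)

    if not _is_contiguous_arc(cationic, all_angles):
        return False, "cationic residues do not occupy a contiguous arc"
    if not _is_contiguous_arc(hydrophobic, all_angles):
        return False, "hydrophobic residues do not occupy a contiguous arc"

    # walk counterclockwise from the interface residue: hydrophobic arc first,
    # then the cationic arc (interface strictly between the two arcs)
    order = sorted(all_angles, key=lambda a: _ccw_distance(w_angle, a))
    assert order[0] == w_angle
    m = formula.hydrophobic_count
    hydro_set, cat_set = set(hydrophobic), set(cationic)
    if not all(a in hydro_set for a in order[1 : m + 1]) or not all(
        a in cat_set for a in order[m + 1 :]
    ):
        return False, (
            "interface residue does not sit between the cationic arc end "
            "and the hydrophobic arc start"
        )
    return True, "perfectly amphipathic"
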