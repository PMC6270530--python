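"""Antimicrobial / hemolytic activity indices.

Implements the geometric-mean MIC (computed in the log2 domain, exact on
two-fold dilution series), hemolysis normalization against a full-lysis
control, the minimal hemolytic concentration (first tested concentration
with strictly more than the threshold % hemolysis), and the
pseudo-therapeutic index TI' = MHC / GM using the *unrounded* GM.

Out-of-range results ("> 128") are carried as explicit :class:`Bound`
markers, never as the numeric limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Bound",
    "MICTable",
    "HemolysisCurve",
    "ActivitySummary",
    "geometric_mean_mic",
    "hemolysis_percent",
    "mhc",
    "pseudo_therapeutic_index",
    "summarize_activity",
]

GRAM_LABELS = ("positive", "negative", "other")


@dataclass(frozen=True)
class Bound:
    """An out-of-range marker, e.g. '> 128 ug/mL'."""

    limit: float

    def __str__(self) -> str:
        return f">{self.limit:g}"

    @classmethod
    def parse(cls, text: str) -> "Bound":
        text = text.strip()
        if not text.startswith(">"):
            raise ValueError(f"not a bound marker: {text!r}")
        return cls(limit=float(text[1:].strip()))


@dataclass
class MICTable:
    """Peptides x strains matrix of MICs (ug/mL) with per-strain Gram labels."""

    peptide_ids: list[str]
    strain_ids: list[str]
    gram_labels: list[str]
    mic: dict[tuple[str, str], float | Bound]  # (peptide_id, strain_id) -> value

    def __post_init__(self) -> None:
        for label in self.gram_labels:
            if label not in GRAM_LABELS:
                raise ValueError(f"unknown gram label {label!r}")
        if len(self.gram_labels) != len(self.strain_ids):
            raise ValueError("one gram label per strain required")
        for pid in self.peptide_ids:
            for sid in self.strain_ids:
                if (pid, sid) not in self.mic:
                    raise ValueError(f"missing MIC cell ({pid}, {sid})")
        for key, value in self.mic.items():
            if isinstance(value, Bound):
                continue
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"MIC cell {key} must be finite and > 0, got {value}")

    def strains_with_gram(self, label: str) -> list[str]:
        return [s for s, g in zip(self.strain_ids, self.gram_labels) if g == label]

    def mics_for(self, peptide_id: str, strains: Iterable[str]) -> list[float | Bound]:
        return [self.mic[(peptide_id, s)] for s in strains]


@dataclass
class HemolysisCurve:
    """Dose-response record: % hemolysis at each tested concentration."""

    peptide_id: str
    concentrations: list[float]
    hemolysis_percent: list[float]

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.hemolysis_percent):
            raise ValueError("concentrations and hemolysis_percent must align")
        if any(b <= a for a, b in zip(self.concentrations, self.concentrations[1:])):
            raise ValueError("concentrations must be strictly ascending")
        for h in self.hemolysis_percent:
            if not -5.0 <= h <= 105.0:
                raise ValueError(f"hemolysis {h}% outside tolerated range [-5, 105]")


@dataclass
class ActivitySummary:
    peptide_id: str
    gm_gram_positive: float
    gm_gram_negative: float
    gm_all: float
    mhc: float | Bound | None
    ti_prime_positive: float | None = None
    ti_prime_negative: float | None = None
    ti_prime_all: float | None = None
    ti_is_lower_bound: bool = field(default=False)


def geometric_mean_mic(mics: Sequence[float | Bound]) -> float:
    """exp(mean(log MIC)), computed in the log2 domain.

    Out-of-range markers are rejected: a bounded cell has no defined GM
    contribution.
    """
    if len(mics) == 0:
        raise ValueError("empty MIC list")
    logs = []
    for value in mics:
        if isinstance(value, Bound):
            raise ValueError(f"cannot take geometric mean over bound marker {value}")
        if not (math.isfinite(value) and value > 0):
            raise ValueError(f"MIC values must be finite and > 0, got {value}")
        logs.append(math.log2(value))
    return 2.0 ** (sum(logs) / len(logs))


def hemolysis_percent(a_sample: float, a_blank: float, a_triton: float) -> float:
    """% hemolysis relative to the full-lysis (Triton) control."""
    if a_triton <= a_blank:
        raise ValueError("degenerate control: a_triton must exceed a_blank")
    return 100.0 * (a_sample - a_blank) / (a_triton - a_blank)


def mhc(curve: HemolysisCurve, threshold: float = 5.0) -> float | Bound:
    """Lowest tested concentration with hemolysis strictly above ``threshold`` %.

    Returns a :class:`Bound` at the highest tested concentration when the
    threshold is never exceeded.
    """
    if not curve.concentrations:
        raise ValueError("empty hemolysis curve")
    for conc, percent in zip(curve.concentrations, curve.hemolysis_percent):
        if percent > threshold:
            return conc
    return Bound(limit=curve.concentrations[-1])


def pseudo_therapeutic_index(
    mhc_value: float | Bound, gm_value: float
) -> tuple[float, bool]:
    """TI' = MHC / GM with the unrounded GM.

    Returns ``(ratio, is_lower_bound)``; a bounded MHC yields a lower bound
    computed at the bound's limit.
    """
    if not (math.isfinite(gm_value) and gm_value > 0):
        raise ValueError(f"GM must be finite and > 0, got {gm_value}")
    if isinstance(mhc_value, Bound):
        return mhc_value.limit / gm_value, True
    return mhc_value / gm_value, False


def summarize_activity(
    table: MICTable,
    curves: Sequence[HemolysisCurve] = (),
    mhc_values: dict[str, float | Bound] | None = None,
    threshold: float = 5.0,
) -> list[ActivitySummary]:
    """Per-peptide GM (Gram-positive / Gram-negative / combined), MHC and TI'.

    MHCs are taken from ``mhc_values`` when given, otherwise derived from the
    hemolysis curves; strains labeled "other" never enter any GM.
    """
    curve_by_id = {c.peptide_id: c for c in curves}
    if mhc_values is None:
        mhc_values = {}
    known_ids = set(table.peptide_ids)
    stray = sorted((set(curve_by_id) | set(mhc_values)) - known_ids)
    if stray:
        raise ValueError(f"peptide ids absent from MIC table: {', '.join(stray)}")

    positive = table.strains_with_gram("positive")
    negative = table.strains_with_gram("negative")

    def gm_or_nan(mics: list[float | Bound]) -> float:
        return geometric_mean_mic(mics) if mics else math.nan

    summaries = []
    for pid in table.peptide_ids:
        gm_pos = gm_or_nan(table.mics_for(pid, positive))
        gm_neg = gm_or_nan(table.mics_for(pid, negative))
        gm_all = geometric_mean_mic(table.mics_for(pid, positive + negative))
        if pid in mhc_values:
            mhc_value: float | Bound | None = mhc_values[pid]
        elif pid in curve_by_id:
            mhc_value = mhc(curve_by_id[pid], threshold=threshold)
        else:
            mhc_value = None
        summary = ActivitySummary(
            peptide_id=pid,
            gm_gram_positive=gm_pos,
            gm_gram_negative=gm_neg,
            gm_all=gm_all,
            mhc=mhc_value,
        )
        if mhc_value is not None:
            for attr, gm in (
                ("ti_prime_positive", gm_pos),
                ("ti_prime_negative", gm_neg),
                ("ti_prime_all", gm_all),
            ):
                if math.isnan(gm):
                    continue
                ratio, bound = pseudo_therapeutic_index(mhc_value, gm)
                setattr(summary, attr, ratio)
                summary.ti_is_lower_bound = bound
        summaries.append(summary)
    return summaries
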