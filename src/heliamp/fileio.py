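"""Readers and writers for the plain-text formats shared by all stages.

Formats:

* FASTA families — headers carry ``|``-separated key=value tags
  (``amide=yes|trp=6|formula=L5K5W``); Biopython does the parsing.
* MIC CSV — rows are strains with a ``gram`` column (positive|negative|other),
  one column per peptide id; cells are ug/mL or a ``>128``-style bound.
* MHC CSV — ``peptide,mhc`` with the same bound convention.
* Hemolysis CSV — long format ``peptide,concentration,percent``.
* Spectrum text — ``# key: value`` metadata header, then two whitespace- or
  comma-delimited columns (wavelength, signal).

The Table 1 / Table 2 panels used by the acceptance suite ship as packaged
fixture CSVs (``mic_panel.csv``, ``mhc_panel.csv``).
"""

from __future__ import annotations

import io
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from heliamp.activity import Bound, HemolysisCurve, MICTable
from heliamp.cd import CDSpectrum, RawSpectrum, SpectrumMetadata
from heliamp.design import (
    DesignedPeptide,
    PeptideFormula,
    wheel_angles,
)
from heliamp.fluor_nmr import EmissionSpectrum

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_mic_csv",
    "read_mhc_csv",
    "read_hemolysis_csv",
    "write_hemolysis_csv",
    "read_spectrum",
    "write_spectrum",
    "read_emission",
    "write_emission",
    "write_activity_summary",
    "load_packaged_mic_table",
    "load_packaged_mhc",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# FASTA

def _parse_formula(tag: str) -> PeptideFormula:
    # e.g. "L5K5W": hydrophobic letter+count, cationic letter+count, interface letter
    import re

    match = re.fullmatch(r"([A-Z])(\d+)([A-Z])(\d+)([A-Z])", tag)
    if not match:
        raise ValueError(f"cannot parse formula tag {tag!r}")
    return PeptideFormula(
        hydrophobic_residue=match.group(1),
        hydrophobic_count=int(match.group(2)),
        cationic_residue=match.group(3),
        cationic_count=int(match.group(4)),
        interface_residue=match.group(5),
    )


def read_fasta(path: str | Path) -> list[DesignedPeptide]:
    """Read a designed family; header tags are parsed when present."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"{path}: empty FASTA, returning no records", stacklevel=2)
        return []
    seen: set[str] = set()
    peptides = []
    for record in records:
        if record.id in seen:
            raise ValueError(f"{path}: duplicate record id {record.id!r}")
        seen.add(record.id)
        sequence = str(record.seq).upper()
        bad = [(i + 1, c) for i, c in enumerate(sequence) if c not in VALID_RESIDUES]
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"{path}: record {record.id!r} has illegal character {char!r} "
                f"at residue {pos}"
            )
        tags = {}
        for chunk in record.description.split("|")[1:]:
            if "=" in chunk:
                key, value = chunk.split("=", 1)
                tags[key.strip()] = value.strip()
        amide = tags.get("amide", "yes").lower() in ("yes", "true", "1")
        trp = int(tags["trp"]) if "trp" in tags else sequence.index("W") + 1
        formula = (
            _parse_formula(tags["formula"]) if "formula" in tags else PeptideFormula()
        )
        peptide = DesignedPeptide(
            sequence=sequence,
            trp_position=trp,
            formula=formula,
            wheel=wheel_angles(len(sequence)),
            c_terminal_amide=amide,
            peptide_id=record.id,
        )
        peptides.append(peptide)
    return peptides


def write_fasta(peptides: list[DesignedPeptide], path: str | Path) -> None:
    records = []
    for p in peptides:
        description = (
            f"{p.peptide_id}|amide={'yes' if p.c_terminal_amide else 'no'}"
            f"|trp={p.trp_position}|formula={p.formula.name}"
        )
        records.append(
            SeqRecord(Seq(p.sequence), id=p.peptide_id, description=description)
        )
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# tables

def _parse_cell(text: str, row: str, column: str) -> float | Bound:
    text = str(text).strip()
    if text.startswith(">"):
        return Bound.parse(text)
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"unparseable numeric cell at row {row!r}, column {column!r}: {text!r}"
        ) from None


def _read_csv(source) -> pd.DataFrame:
    return pd.read_csv(source, comment="#", dtype=str, skipinitialspace=True)


def _mic_table_from_frame(frame: pd.DataFrame, origin: str) -> MICTable:
    for required in ("strain", "gram"):
        if required not in frame.columns:
            raise ValueError(f"{origin}: missing required column {required!r}")
    peptide_ids = [c for c in frame.columns if c not in ("strain", "gram")]
    strain_ids = frame["strain"].tolist()
    gram_labels = frame["gram"].str.strip().str.lower().tolist()
    mic: dict[tuple[str, str], float | Bound] = {}
    for _, row in frame.iterrows():
        for pid in peptide_ids:
            mic[(pid, row["strain"])] = _parse_cell(row[pid], row["strain"], pid)
    return MICTable(
        peptide_ids=peptide_ids, strain_ids=strain_ids, gram_labels=gram_labels, mic=mic
    )


def read_mic_csv(path: str | Path) -> MICTable:
    return _mic_table_from_frame(_read_csv(path), str(path))


def read_mhc_csv(path: str | Path) -> dict[str, float | Bound]:
    frame = _read_csv(path)
    for required in ("peptide", "mhc"):
        if required not in frame.columns:
            raise ValueError(f"{path}: missing required column {required!r}")
    return {
        row["peptide"]: _parse_cell(row["mhc"], row["peptide"], "mhc")
        for _, row in frame.iterrows()
    }


def read_hemolysis_csv(path: str | Path) -> list[HemolysisCurve]:
    frame = _read_csv(path)
    for required in ("peptide", "concentration", "percent"):
        if required not in frame.columns:
            raise ValueError(f"{path}: missing required column {required!r}")
    curves = []
    for pid, group in frame.groupby("peptide", sort=False):
        group = group.assign(
            concentration=group["concentration"].astype(float),
            percent=group["percent"].astype(float),
        ).sort_values("concentration")
        curves.append(
            HemolysisCurve(
                peptide_id=str(pid),
                concentrations=group["concentration"].tolist(),
                hemolysis_percent=group["percent"].tolist(),
            )
        )
    return curves


def write_hemolysis_csv(curves: list[HemolysisCurve], path: str | Path) -> None:
    rows = [
        {"peptide": c.peptide_id, "concentration": conc, "percent": pct}
        for c in curves
        for conc, pct in zip(c.concentrations, c.hemolysis_percent)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_activity_summary(summaries, path: str | Path, decimals: int = 1) -> None:
    """Summary CSV mirroring the GM / MHC / TI' table layout (rounded for display)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "peptide": s.peptide_id,
                "gm_gram_positive": round(s.gm_gram_positive, decimals),
                "gm_gram_negative": round(s.gm_gram_negative, decimals),
                "gm_all": round(s.gm_all, decimals),
                "mhc": str(s.mhc) if s.mhc is not None else "",
                "ti_prime_positive": (
                    round(s.ti_prime_positive, decimals) if s.ti_prime_positive else ""
                ),
                "ti_prime_negative": (
                    round(s.ti_prime_negative, decimals) if s.ti_prime_negative else ""
                ),
                "ti_prime_all": round(s.ti_prime_all, decimals) if s.ti_prime_all else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spectra

def _write_two_column(path: Path, header: dict[str, str], x, y) -> None:
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {value}\n")
        for a, b in zip(x, y):
            fh.write(f"{a:.6g}\t{b:.10g}\n")


def _read_two_column(path: Path) -> tuple[dict[str, str], np.ndarray, np.ndarray]:
    header: dict[str, str] = {}
    xs, ys = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, value = body.split(":", 1)
                header[key.strip()] = value.strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    return header, np.asarray(xs), np.asarray(ys)


def write_spectrum(spectrum: RawSpectrum | CDSpectrum, path: str | Path) -> None:
    md = spectrum.metadata
    header = {
        "concentration_M": f"{md.concentration_molar:.8g}",
        "path_cm": f"{md.path_cm:g}",
        "n_residues": str(md.n_residues),
        "solvent": md.solvent,
        "label": md.label,
        "units": "mdeg" if isinstance(spectrum, RawSpectrum) else "deg.cm2.dmol-1",
    }
    y = spectrum.signal_mdeg if isinstance(spectrum, RawSpectrum) else spectrum.theta
    _write_two_column(Path(path), header, spectrum.wavelengths, y)


def read_spectrum(path: str | Path) -> RawSpectrum | CDSpectrum:
    header, x, y = _read_two_column(Path(path))
    for required in ("concentration_M", "path_cm", "n_residues"):
        if required not in header:
            raise ValueError(f"{path}: missing metadata line {required!r}")
    metadata = SpectrumMetadata(
        concentration_molar=float(header["concentration_M"]),
        path_cm=float(header["path_cm"]),
        n_residues=int(header["n_residues"]),
        solvent=header.get("solvent", ""),
        label=header.get("label", ""),
    )
    if header.get("units", "mdeg") == "mdeg":
        return RawSpectrum(wavelengths=x, signal_mdeg=y, metadata=metadata)
    return CDSpectrum(wavelengths=x, theta=y, metadata=metadata)


def write_emission(spectrum: EmissionSpectrum, path: str | Path) -> None:
    _write_two_column(
        Path(path), {"label": spectrum.label}, spectrum.wavelengths, spectrum.intensity
    )


def read_emission(path: str | Path) -> EmissionSpectrum:
    header, x, y = _read_two_column(Path(path))
    return EmissionSpectrum(wavelengths=x, intensity=y, label=header.get("label", ""))


# ---------------------------------------------------------------------------
# packaged fixtures

def _packaged(name: str) -> io.StringIO:
    return io.StringIO((resources.files("heliamp.data") / name).read_text())


def load_packaged_mic_table() -> MICTable:
    """The 11-peptide x 10-strain MIC panel shipped with the package."""
    return _mic_table_from_frame(_read_csv(_packaged("mic_panel.csv")), "mic_panel.csv")


def load_packaged_mhc() -> dict[str, float | Bound]:
    """The matching minimal-hemolytic-concentration panel."""
    frame = _read_csv(_packaged("mhc_panel.csv"))
    return {
        row["peptide"]: _parse_cell(row["mhc"], row["peptide"], "mhc")
        for _, row in frame.iterrows()
    }
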