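"""Readers and writers: MGF peak lists, FASTA, identification tables.

MGF parsing is backed by pyteomics; a structural pre-scan adds the line
numbers pyteomics does not track, so malformed blocks are reported where
they occur. m/z values are written at 4 decimals; residue and fragment
indices are 1-based everywhere.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _mgf

from .masschem import (
    RESIDUE_MASSES,
    ModifiedPeptide,
    default_modifications,
)
from .matching import MatchReport, Spectrum

__all__ = ["read_mgf", "write_mgf", "read_fasta", "read_identifications",
           "write_identifications", "peptide_from_row", "write_annotations"]

log = logging.getLogger("phosphoval")


def _prescan_mgf(path: Path) -> None:
    """Structural validation with line numbers: BEGIN/END pairing and a
    PEPMASS line inside every block."""
    open_line = None
    has_pepmass = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line == "BEGIN IONS":
            if open_line is not None:
                raise ValueError(
                    f"{path}:{lineno}: BEGIN IONS inside block opened at "
                    f"line {open_line}")
            open_line, has_pepmass = lineno, False
        elif line == "END IONS":
            if open_line is None:
                raise ValueError(f"{path}:{lineno}: END IONS without BEGIN IONS")
            if not has_pepmass:
                raise ValueError(
                    f"{path}:{open_line}: block missing PEPMASS "
                    f"(ends at line {lineno})")
            open_line = None
        elif line.startswith("PEPMASS"):
            has_pepmass = True
    if open_line is not None:
        raise ValueError(f"{path}:{open_line}: unterminated BEGIN IONS block")


def read_mgf(path: str | Path, default_charge: int = 2) -> list[Spectrum]:
    """Parse an MGF file into Spectrum objects.

    A missing CHARGE line falls back to ``default_charge`` with a logged
    warning; a missing PEPMASS is a hard error naming the line.
    """
    path = Path(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        log.warning("%s: empty MGF file", path)
        return []
    _prescan_mgf(path)
    out: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for entry in reader:
            params = entry["params"]
            title = params.get("title", "")
            pepmass = params["pepmass"][0]
            charge_field = params.get("charge")
            if charge_field:
                charge = int(charge_field[0])
            else:
                charge = default_charge
                log.warning("%s: spectrum %r has no CHARGE; assuming %d+",
                            path, title, charge)
            peaks = tuple(zip(entry["m/z array"].tolist(),
                              entry["intensity array"].tolist()))
            out.append(Spectrum(precursor_mz=float(pepmass),
                                precursor_charge=charge, peaks=peaks,
                                title=title))
    return out


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as standard MGF, m/z at 4 decimals."""
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.title}")
        lines.append(f"PEPMASS={s.precursor_mz:.4f}")
        lines.append(f"CHARGE={s.precursor_charge}+")
        for mz, inten in s.peaks:
            lines.append(f"{mz:.4f} {inten:.2f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read protein records; sequences upper-cased, restricted to the 20
    standard residues; duplicate identifiers rejected."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"{path}: duplicate identifier {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in RESIDUE_MASSES:
                raise ValueError(
                    f"{path}: record {record.id!r} has non-standard "
                    f"residue {ch!r} at offset {i + 1}")
        out.append((record.id, seq))
    return out


# -- identification tables --------------------------------------------------

def peptide_from_row(sequence: str, mods: str) -> ModifiedPeptide:
    """Build a ModifiedPeptide from table fields; mods formatted as
    ``Name@pos`` joined by ``;`` (pos = 1-based index or terminus marker)."""
    registry = default_modifications()
    parsed = []
    if mods and not pd.isna(mods):
        for token in str(mods).split(";"):
            token = token.strip()
            if not token:
                continue
            name, _, pos = token.partition("@")
            if name not in registry:
                raise ValueError(f"unknown modification {name!r}")
            parsed.append(
                (pos if pos in ("N-term", "C-term") else int(pos),
                 registry[name]))
    return ModifiedPeptide(sequence, tuple(parsed))


def read_identifications(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mods": str}, keep_default_na=False)
    required = {"title", "sequence", "mods", "charge"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_identifications(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_annotations(report: MatchReport, path: str | Path) -> None:
    """Annotated-spectrum dump for manual inspection."""
    rows = [{
        "peak_mz": f"{a.peak_mz:.4f}",
        "intensity": f"{a.peak_intensity:.2f}",
        "ion": a.ion.label,
        "delta_mz": f"{a.delta_mz:+.4f}",
    } for a in report.assignments]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
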