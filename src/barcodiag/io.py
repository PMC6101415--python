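"""Readers and writers for the external formats the toolkit speaks.

FASTA (plain and aligned) and Clustal parsing go through Biopython; this
module adds the species-label plumbing, strict IUPAC validation with
record/offset diagnostics, and gap normalisation ('.', '~' -> '-').

Species labels come either from a FASTA header convention ``id|species|locus``
or from an explicit TSV label map (columns: id, species, locus), the map
winning where both are present — GenBank-derived headers vary too much for
anything less explicit.
"""

from __future__ import annotations

import csv
import json
import os
from typing import Iterable, Mapping

from Bio import AlignIO, SeqIO

from .errors import (
    AlignmentLengthError,
    DuplicateIdError,
    EmptyInputError,
    FormatError,
)
from .records import Alignment, SeqRecord, SpeciesPanel

_GAP_NORMALISE = str.maketrans(".~", "--")

FASTA_WRAP = 70


def _parse_header(header: str) -> tuple[str, str | None, str | None]:
    """Split an ``id|species|locus`` header; missing fields become None."""
    parts = header.split("|")
    rec_id = parts[0].strip()
    species = parts[1].strip() or None if len(parts) > 1 else None
    locus = parts[2].strip() or None if len(parts) > 2 else None
    return rec_id, species, locus


def read_label_map(path: str | os.PathLike) -> dict[str, tuple[str, str | None]]:
    """Read a TSV label map (id, species[, locus]) -> {id: (species, locus)}."""
    out: dict[str, tuple[str, str | None]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() == "id" and lineno == 1:
                continue  # header line
            if len(row) < 2:
                raise FormatError(f"label map line {lineno}: need id<TAB>species")
            rec_id = row[0].strip()
            if rec_id in out:
                raise DuplicateIdError(f"label map: duplicate id {rec_id!r}")
            locus = row[2].strip() if len(row) > 2 and row[2].strip() else None
            out[rec_id] = (row[1].strip(), locus)
    return out


def _records_from_fasta(path: str | os.PathLike, *, aligned: bool) -> list[SeqRecord]:
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id, species, locus = _parse_header(rec.description)
        if rec_id in seen:
            raise DuplicateIdError(f"{path}: duplicate id {rec_id!r}")
        seen.add(rec_id)
        residues = str(rec.seq).translate(_GAP_NORMALISE)
        sr = SeqRecord(rec_id, residues, species, locus).validated(aligned=aligned)
        records.append(sr)
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    return records


def _apply_label_map(
    records: list[SeqRecord], label_map: Mapping[str, tuple[str, str | None]]
) -> list[SeqRecord]:
    out = []
    for r in records:
        if r.id in label_map:
            species, locus = label_map[r.id]
            out.append(SeqRecord(r.id, r.residues, species, locus or r.locus))
        else:
            out.append(r)
    return out


def read_fasta(
    path: str | os.PathLike,
    label_map: str | os.PathLike | None = None,
    locus: str | None = None,
) -> SpeciesPanel:
    """Read a species-labelled FASTA file into a :class:`SpeciesPanel`.

    Species come from the ``id|species|locus`` header convention, overridden
    by an optional TSV label map.  Every record must end up labelled.
    """
    records = _records_from_fasta(path, aligned=False)
    if label_map is not None:
        records = _apply_label_map(records, read_label_map(label_map))
    return SpeciesPanel(records, locus=locus)


def write_fasta(
    records: Iterable[SeqRecord] | SpeciesPanel,
    path: str | os.PathLike,
    *,
    wrap: int = FASTA_WRAP,
) -> None:
    """Write records as FASTA with ``id|species|locus`` headers, wrapped."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.species is not None or rec.locus is not None:
                header += f"|{rec.species or ''}"
            if rec.locus is not None:
                header += f"|{rec.locus}"
            fh.write(f">{header}\n")
            seq = rec.residues
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_alignment(
    path: str | os.PathLike,
    dialect: str = "fasta",
    label_map: str | os.PathLike | None = None,
) -> Alignment:
    """Read an alignment (``fasta`` or ``clustal``) into :class:`Alignment`.

    Gap characters '.', '~' are normalised to '-'.  Ragged FASTA rows raise
    :class:`AlignmentLengthError` naming the offending ids.
    """
    if dialect not in ("fasta", "clustal"):
        raise FormatError(f"unknown alignment dialect {dialect!r}")
    if dialect == "fasta":
        records = _records_from_fasta(path, aligned=True)
    else:
        try:
            msa = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise FormatError(f"{path}: not a Clustal alignment ({exc})") from exc
        records = []
        seen: set[str] = set()
        for rec in msa:
            rec_id, species, locus = _parse_header(rec.id)
            if rec_id in seen:
                raise DuplicateIdError(f"{path}: duplicate id {rec_id!r}")
            seen.add(rec_id)
            residues = str(rec.seq).translate(_GAP_NORMALISE)
            records.append(
                SeqRecord(rec_id, residues, species, locus).validated(aligned=True)
            )
        if not records:
            raise EmptyInputError(f"{path}: no alignment rows")
    if label_map is not None:
        records = _apply_label_map(records, read_label_map(label_map))
    return Alignment(records)


def write_alignment(
    alignment: Alignment, path: str | os.PathLike, dialect: str = "fasta"
) -> None:
    """Write an alignment as aligned FASTA or Clustal."""
    if dialect == "fasta":
        write_fasta(alignment, path)
    elif dialect == "clustal":
        fh = open(path, "w")
        with fh:
            fh.write("CLUSTAL W multiple sequence alignment\n\n")
            width = 60
            names = [r.id for r in alignment.rows]
            pad = max(len(n) for n in names) + 3
            for start in range(0, alignment.length, width):
                for r in alignment.rows:
                    fh.write(f"{r.id:<{pad}}{r.residues[start:start + width]}\n")
                fh.write("\n")
    else:
        raise FormatError(f"unknown alignment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Primer panel tables


def read_primer_panel(path: str | os.PathLike):
    """Read a primer panel from JSON (see :func:`write_primer_panel`)."""
    from .primers import Primer, PrimerPanel

    with open(path) as fh:
        doc = json.load(fh)
    primers = [
        Primer(
            name=p["name"],
            sequence=p["sequence"],
            orientation=p.get("orientation", "forward"),
            role=p["role"],
            target_species=p.get("target_species"),
            specific_3prime_len=int(p.get("specific_3prime_len", 0)),
        )
        for p in doc["primers"]
    ]
    expected = {sp: [int(b) for b in bands] for sp, bands in doc["expected_bands"].items()}
    return PrimerPanel(
        primers=primers,
        expected_bands=expected,
        control_band=int(doc["control_band"]),
    )


def write_primer_panel(panel, path: str | os.PathLike) -> None:
    doc = {
        "primers": [
            {
                "name": p.name,
                "role": p.role,
                "orientation": p.orientation,
                "target_species": p.target_species,
                "sequence": p.sequence,
                "specific_3prime_len": p.specific_3prime_len,
                "tm_wallace": p.tm_wallace,
                "gc_percent": p.gc_percent,
            }
            for p in panel.primers
        ],
        "expected_bands": panel.expected_bands,
        "control_band": panel.control_band,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def write_band_report(calls, path: str | os.PathLike, header_lines=()) -> None:
    """Write per-sample band/call rows as TSV (sample, band_sizes, call)."""
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "band_sizes", "call"])
        for call in calls:
            writer.writerow(
                [call.sample_id, ",".join(str(b) for b in call.bands), call.call]
            )
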