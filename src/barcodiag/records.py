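"""Core in-memory containers: sequence records, species panels, alignments.

Conventions used throughout the package:

* residues are upper-case IUPAC DNA (``ACGTRYSWKMBDHVN``) plus ``-`` for a
  gap in aligned context;
* alignment columns are addressed 1-based inclusive, matching the way
  diagnostic positions are reported in the barcoding literature
  (e.g. "positions 560-561");
* species labels are free text; every record in a :class:`SpeciesPanel`
  must carry one.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import (
    AlignmentLengthError,
    ContractError,
    DuplicateIdError,
    FormatError,
    UnknownSpeciesError,
)

IUPAC_BASES = frozenset("ACGT")
GAP = "-"

#: IUPAC code -> set of unambiguous bases it may stand for.
IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: frozenset of bases -> IUPAC code (inverse of IUPAC_SETS).
SETS_IUPAC: Mapping[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

IUPAC_ALPHABET = frozenset(IUPAC_SETS) | {GAP}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (gap maps to gap)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_residues(residues: str, *, record_id: str, allow_gaps: bool) -> str:
    """Upper-case and validate a residue string; return the cleaned string.

    Raises :class:`FormatError` naming the record and 1-based offset of the
    first illegal character.
    """
    cleaned = residues.upper()
    if not cleaned:
        raise FormatError(f"record {record_id!r}: empty residue string")
    legal = IUPAC_ALPHABET if allow_gaps else frozenset(IUPAC_SETS)
    for i, ch in enumerate(cleaned, start=1):
        if ch not in legal:
            raise FormatError(
                f"record {record_id!r}: illegal character {ch!r} at offset {i}"
            )
    return cleaned


@dataclass(frozen=True)
class SeqRecord:
    """One DNA sequence with optional species/locus annotation.

    ``residues`` may contain ``-`` only when the record belongs to an
    alignment (``aligned=True`` at validation time).
    """

    id: str
    residues: str
    species: str | None = None
    locus: str | None = None

    def validated(self, *, aligned: bool = False) -> "SeqRecord":
        cleaned = validate_residues(self.residues, record_id=self.id, allow_gaps=aligned)
        if cleaned is self.residues:
            return self
        return SeqRecord(self.id, cleaned, self.species, self.locus)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


class SpeciesPanel:
    """Species-labelled barcode sequences for one locus.

    The unit of all downstream analysis.  Every record must carry a species
    label; record ids are unique.
    """

    def __init__(self, records: Iterable[SeqRecord], locus: str | None = None):
        self.records: list[SeqRecord] = []
        self._by_id: "OrderedDict[str, SeqRecord]" = OrderedDict()
        self.species_index: "OrderedDict[str, list[str]]" = OrderedDict()
        for rec in records:
            if rec.id in self._by_id:
                raise DuplicateIdError(f"duplicate record id {rec.id!r}")
            if rec.species is None:
                raise FormatError(f"record {rec.id!r} has no species label")
            self._by_id[rec.id] = rec
            self.records.append(rec)
            self.species_index.setdefault(rec.species, []).append(rec.id)
        self.locus = locus or next(
            (r.locus for r in self.records if r.locus is not None), None
        )

    @property
    def species(self) -> list[str]:
        return list(self.species_index)

    @property
    def n_species(self) -> int:
        return len(self.species_index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> SeqRecord:
        try:
            return self._by_id[record_id]
        except KeyError:
            raise UnknownSpeciesError(f"no record with id {record_id!r}") from None

    def records_for(self, species: str) -> list[SeqRecord]:
        try:
            ids = self.species_index[species]
        except KeyError:
            raise UnknownSpeciesError(f"species {species!r} not in panel") from None
        return [self._by_id[i] for i in ids]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpeciesPanel):
            return NotImplemented
        return self.locus == other.locus and [
            (r.id, r.species, r.residues) for r in self.records
        ] == [(r.id, r.species, r.residues) for r in other.records]


class Alignment:
    """Equal-length residue rows with species labels; 1-based columns."""

    def __init__(self, rows: Iterable[SeqRecord]):
        self.rows: list[SeqRecord] = [r.validated(aligned=True) for r in rows]
        if not self.rows:
            raise AlignmentLengthError("alignment has no rows")
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) > 1:
            longest = max(lengths)
            bad = [r.id for r in self.rows if len(r.residues) != longest]
            raise AlignmentLengthError(
                f"rows of unequal length (expected {longest}): {', '.join(bad)}"
            )
        seen: set[str] = set()
        for r in self.rows:
            if r.id in seen:
                raise DuplicateIdError(f"duplicate row id {r.id!r}")
            seen.add(r.id)
        self.length: int = len(self.rows[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for r in self.rows:
            if r.species is not None and r.species not in out:
                out.append(r.species)
        return out

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.rows)

    def row(self, row_id: str) -> SeqRecord:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise UnknownSpeciesError(f"no row with id {row_id!r}")

    def rows_for(self, species: str) -> list[SeqRecord]:
        out = [r for r in self.rows if r.species == species]
        if not out:
            raise UnknownSpeciesError(f"species {species!r} not in alignment")
        return out

    def column(self, col: int) -> str:
        """States of 1-based column ``col``, one character per row."""
        if not 1 <= col <= self.length:
            raise ContractError(f"column {col} outside 1..{self.length}")
        i = col - 1
        return "".join(r.residues[i] for r in self.rows)

    def slice_columns(self, start: int, end: int) -> "Alignment":
        """Sub-alignment over 1-based inclusive columns [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ContractError(f"bad column range {start}..{end} for L={self.length}")
        return Alignment(
            SeqRecord(r.id, r.residues[start - 1 : end], r.species, r.locus)
            for r in self.rows
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return [(r.id, r.species, r.residues) for r in self.rows] == [
            (r.id, r.species, r.residues) for r in other.rows
        ]
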