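"""Per-locus barcode descriptors: ungapped length, GC content, variability.

GC content counts G, C and the two-fold code S (G or C) over non-gap bases;
other ambiguity codes enter the denominator only, which keeps the statistic
deterministic on IUPAC input.

Percent variation is column-wise: the fraction of alignment columns whose
rows do not all share one state, with the gap treated as a fifth character
state (indel-rich spacers like ITS2 owe most of their signal to insertions/
deletions, so indel columns must count) and columns that are gap in every
row dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import InsufficientDataError, UndefinedValueError, UnknownSpeciesError
from .records import GAP, Alignment, SpeciesPanel


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (so 2.345 -> 2.35, not banker's 2.34)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_percent(residues: str) -> float:
    """GC content of a DNA string, in percent.

    100 * (#G + #C + #S) / (#non-gap bases).  Raises
    :class:`UndefinedValueError` on all-gap input.
    """
    seq = residues.upper()
    non_gap = sum(1 for ch in seq if ch != GAP)
    if non_gap == 0:
        raise UndefinedValueError("GC content undefined on all-gap input")
    gc = sum(1 for ch in seq if ch in "GCS")
    return 100.0 * gc / non_gap


def variation_percent(alignment: Alignment, ndigits: int | None = None) -> float:
    """Percent of variable columns in a species-labelled alignment.

    A column is variable when its rows do not all share one identical state;
    '-' counts as a fifth state.  Columns that are gap in every row are
    excluded from numerator and denominator.  ``ndigits`` applies half-up
    rounding to the result (None = full precision).
    """
    if len(alignment) < 2:
        raise InsufficientDataError("variation requires at least 2 rows")
    retained = 0
    variable = 0
    rows = [r.residues for r in alignment.rows]
    for i in range(alignment.length):
        states = {row[i] for row in rows}
        if states == {GAP}:
            continue
        retained += 1
        if len(states) > 1:
            variable += 1
    if retained == 0:
        raise UndefinedValueError("alignment is entirely gap columns")
    value = 100.0 * variable / retained
    return round_half_up(value, ndigits) if ndigits is not None else value


@dataclass
class LocusStats:
    """Length/GC per species plus one panel-level variation figure."""

    locus: str | None
    per_species: dict[str, tuple[int, float]]  # species -> (length_bp, gc_percent)
    variation_percent: float
    n_columns: int


def locus_summary(
    panel: SpeciesPanel, alignment: Alignment, ndigits: int = 2
) -> LocusStats:
    """Per-species ungapped length and GC plus panel variation.

    Length and GC are computed on the ungapped residues of one representative
    record per species (the first record carrying that label, i.e. the
    accessioned voucher in a curated panel).  Raises
    :class:`UnknownSpeciesError` when a panel species has no alignment row.
    """
    aligned_species = set(alignment.species)
    per_species: dict[str, tuple[int, float]] = {}
    for species in panel.species:
        if species not in aligned_species:
            raise UnknownSpeciesError(
                f"species {species!r} present in panel but absent from alignment"
            )
        rep = panel.records_for(species)[0]
        seq = rep.ungapped
        per_species[species] = (len(seq), round_half_up(gc_percent(seq), ndigits))
    return LocusStats(
        locus=panel.locus,
        per_species=per_species,
        variation_percent=variation_percent(alignment, ndigits=ndigits),
        n_columns=alignment.length,
    )
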