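"""Species-diagnostic site and motif detection in a labelled alignment.

A column is diagnostic for a target species when (i) every target row shares
one unambiguous state (A/C/G/T or the gap) and (ii) that state is absent
from every non-target row — strict character-based diagnosis, the rule under
which an allele-specific primer anchored on the site is refractory in all
other species.  A non-target IUPAC ambiguity whose base set contains the
candidate allele breaks diagnosis: a primer must never sit on an uncertain
base.

Intraspecific heterogeneity is handled the way barcoding practice handles
it: collapse each species to its consensus first (:func:`species_consensus`)
or relax fixation with ``min_target_freq``.

Coordinates are 1-based inclusive alignment columns, and always refer to the
alignment actually analysed — never to coordinates from some other
alignment of the same locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError, InsufficientDataError, UnknownSpeciesError
from .records import GAP, IUPAC_SETS, SETS_IUPAC, Alignment, SeqRecord

_PLAIN_STATES = frozenset("ACGT-")


@dataclass(frozen=True)
class DiagnosticMotif:
    """An alignment interval fixed in one species and absent elsewhere."""

    target_species: str
    start: int  # 1-based inclusive
    end: int
    target_allele: str  # over {A,C,G,T,-}, one char per column
    background_alleles: frozenset[str] = field(default_factory=frozenset)
    fixed_in_target: bool = True

    def __post_init__(self):
        if self.start > self.end:
            raise ContractError("motif start > end")
        if len(self.target_allele) != self.end - self.start + 1:
            raise ContractError("allele length does not match interval width")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def is_gap(self) -> bool:
        return set(self.target_allele) == {GAP}


def _column_diagnostic_state(
    target_states: str, other_states: str, min_target_freq: float
) -> str | None:
    """Return the diagnostic state of one column, or None.

    ``target_states``/``other_states`` are the column characters of target
    and non-target rows.  With ``min_target_freq`` < 1 the majority target
    state qualifies if carried by at least that fraction of target rows and
    if no other state segregates in the target (ambiguities never qualify).
    """
    counts: dict[str, int] = {}
    for ch in target_states:
        counts[ch] = counts.get(ch, 0) + 1
    cand, n_cand = max(sorted(counts.items()), key=lambda kv: kv[1])
    if cand not in _PLAIN_STATES:
        return None
    if n_cand / len(target_states) < min_target_freq:
        return None
    if min_target_freq >= 1.0 and n_cand != len(target_states):
        return None
    for ch in other_states:
        if ch == cand:
            return None
        if ch in IUPAC_SETS and cand in IUPAC_SETS.get(ch, frozenset()):
            # non-target ambiguity may stand for the candidate base
            return None
    return cand


def find_diagnostic_sites(
    alignment: Alignment, target_species: str, min_target_freq: float = 1.0
) -> list[DiagnosticMotif]:
    """All single columns diagnostic for ``target_species``.

    Returns one width-1 :class:`DiagnosticMotif` per qualifying column, in
    column order.
    """
    species = alignment.species
    if len(species) < 2:
        raise InsufficientDataError("diagnosis requires >= 2 species")
    if target_species not in species:
        raise UnknownSpeciesError(f"species {target_species!r} not in alignment")
    target_rows = [r.residues for r in alignment.rows if r.species == target_species]
    other_rows = [r.residues for r in alignment.rows if r.species != target_species]
    sites: list[DiagnosticMotif] = []
    for i in range(alignment.length):
        tgt = "".join(row[i] for row in target_rows)
        oth = "".join(row[i] for row in other_rows)
        state = _column_diagnostic_state(tgt, oth, min_target_freq)
        if state is not None:
            sites.append(
                DiagnosticMotif(
                    target_species=target_species,
                    start=i + 1,
                    end=i + 1,
                    target_allele=state,
                    background_alleles=frozenset(oth),
                )
            )
    return sites


def merge_adjacent(sites: list[DiagnosticMotif], alignment: Alignment | None = None) -> list[DiagnosticMotif]:
    """Merge runs of consecutive diagnostic columns into multi-base motifs.

    All sites must share one target species.  When ``alignment`` is given,
    background alleles of merged motifs are re-read from the non-target rows
    over the merged interval; otherwise they are the union of per-site
    backgrounds.
    """
    if not sites:
        return []
    species = {s.target_species for s in sites}
    if len(species) > 1:
        raise ContractError(f"sites target multiple species: {sorted(species)}")
    target = sites[0].target_species
    ordered = sorted(sites, key=lambda s: s.start)
    merged: list[DiagnosticMotif] = []
    run = [ordered[0]]
    for site in ordered[1:]:
        if site.start == run[-1].end + 1:
            run.append(site)
        else:
            merged.append(_merge_run(run, target, alignment))
            run = [site]
    merged.append(_merge_run(run, target, alignment))
    return merged


def _merge_run(
    run: list[DiagnosticMotif], target: str, alignment: Alignment | None
) -> DiagnosticMotif:
    start, end = run[0].start, run[-1].end
    allele = "".join(s.target_allele for s in run)
    if alignment is not None:
        background = frozenset(
            r.residues[start - 1 : end]
            for r in alignment.rows
            if r.species != target
        )
    else:
        background = frozenset().union(*(s.background_alleles for s in run))
    return DiagnosticMotif(
        target_species=target,
        start=start,
        end=end,
        target_allele=allele,
        background_alleles=background,
    )


def diagnostic_report(
    alignment: Alignment, min_target_freq: float = 1.0
) -> dict[str, dict]:
    """Per-species merged motifs plus an ``assayable`` flag.

    A species is assayable when at least one of its motifs ends on a non-gap
    allele — the requirement for anchoring an allele-specific primer's 3'
    terminus on the motif.
    """
    species = alignment.species
    if len(species) < 2:
        raise InsufficientDataError("diagnosis requires >= 2 species")
    report: dict[str, dict] = {}
    for sp in species:
        sites = find_diagnostic_sites(alignment, sp, min_target_freq)
        motifs = merge_adjacent(sites, alignment) if sites else []
        assayable = any(m.target_allele[-1] != GAP for m in motifs)
        report[sp] = {"motifs": motifs, "assayable": assayable}
    return report


def species_consensus(alignment: Alignment, species: str | None = None) -> Alignment:
    """Collapse each species to one consensus row (majority state per column).

    Ties among bases become the IUPAC ambiguity code of the tied set; a tie
    involving the gap resolves to the tied base(s) — ambiguity codes cannot
    express indel uncertainty, and keeping the base is the conservative
    choice for primer design.  With ``species`` given, only that label is
    collapsed and other rows pass through.
    """
    targets = [species] if species is not None else alignment.species
    if species is not None and species not in alignment.species:
        raise UnknownSpeciesError(f"species {species!r} not in alignment")
    rows: list[SeqRecord] = []
    done: set[str] = set()
    for r in alignment.rows:
        if r.species in targets:
            if r.species in done:
                continue
            done.add(r.species)
            members = [x.residues for x in alignment.rows if x.species == r.species]
            rows.append(
                SeqRecord(
                    id=f"{r.species}/consensus",
                    residues=_consensus_residues(members),
                    species=r.species,
                    locus=r.locus,
                )
            )
        else:
            rows.append(r)
    return Alignment(rows)


def _consensus_residues(rows: list[str]) -> str:
    out: list[str] = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        top = max(counts.values())
        tied = sorted(ch for ch, n in counts.items() if n == top)
        if len(tied) == 1:
            out.append(tied[0])
            continue
        bases: set[str] = set()
        for ch in tied:
            if ch in IUPAC_SETS:
                bases |= IUPAC_SETS[ch]
        if not bases:  # tie among gaps only
            out.append(GAP)
        else:
            out.append(SETS_IUPAC.get(frozenset(bases), "N"))
    return "".join(out)
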