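"""Allele-specific (ARMS) multiplex primer design on diagnostic motifs.

Species-specific forward primers are drawn from the target species'
consensus and end exactly on the 3'-most base of a diagnostic motif, so a
single 3'-terminal mismatch makes them refractory on every other species.
A universal control pair sits in fully conserved windows bracketing the
variable region, so every species-specific amplicon nests inside the
control amplicon and "no template" is distinguishable from "non-target".

Melting temperatures use the Wallace rule, Tm = 2(A+T) + 4(G+C) °C —
adequate for the 15-25-mers designed here and fully deterministic; no
thermodynamic tables are consulted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .diagnostics import DiagnosticMotif, species_consensus
from .errors import ContractError, NoPrimerError, ParameterError
from .records import GAP, Alignment, reverse_complement
from .stats import gc_percent

_UNAMBIG = frozenset("ACGT")


def wallace_tm(sequence: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C), in °C."""
    seq = sequence.upper()
    if not seq:
        raise ContractError("empty primer sequence")
    bad = set(seq) - _UNAMBIG
    if bad:
        raise ContractError(f"ambiguous base(s) {sorted(bad)} in primer sequence")
    at = sum(1 for ch in seq if ch in "AT")
    return 2.0 * at + 4.0 * (len(seq) - at)


@dataclass(frozen=True)
class Primer:
    """A single oligo with its role in the multiplex panel."""

    name: str
    sequence: str  # 5'->3', unambiguous
    orientation: str = "forward"  # forward | reverse
    role: str = "species_specific"  # species_specific | universal_forward | universal_reverse
    target_species: str | None = None
    specific_3prime_len: int = 0
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _UNAMBIG
        if bad:
            raise ContractError(
                f"primer {self.name!r}: ambiguous base(s) {sorted(bad)}"
            )
        if self.specific_3prime_len > len(seq):
            raise ContractError("specific_3prime_len exceeds primer length")
        if self.orientation not in ("forward", "reverse"):
            raise ContractError(f"bad orientation {self.orientation!r}")

    @property
    def tm_wallace(self) -> float:
        return wallace_tm(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_percent(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DesignConstraints:
    """Knobs of the designer; defaults suit a 52 °C multiplex annealing."""

    len_range: tuple[int, int] = (15, 25)
    tm_range: tuple[float, float] = (48.0, 62.0)
    gc_range: tuple[float, float] = (30.0, 80.0)
    max_3prime_cross_complement: int = 4
    min_band_separation: int = 30

    def __post_init__(self):
        if self.len_range[0] >= self.len_range[1] or self.tm_range[0] >= self.tm_range[1]:
            raise ParameterError("degenerate constraint range")


@dataclass
class PrimerPanel:
    """Primers plus the expected band table used by the species caller."""

    primers: list[Primer]
    expected_bands: dict[str, list[int]]  # species -> ordered band sizes (bp)
    control_band: int

    def __post_init__(self):
        n_rev = sum(1 for p in self.primers if p.role == "universal_reverse")
        if n_rev != 1:
            raise ContractError(f"panel needs exactly one universal_reverse, got {n_rev}")
        species_bands = [b for bands in self.expected_bands.values() for b in bands]
        if len(set(species_bands)) != len(species_bands):
            raise ContractError("species expected bands are not distinct")

    @property
    def universal_reverse(self) -> Primer:
        return next(p for p in self.primers if p.role == "universal_reverse")

    @property
    def species_primers(self) -> list[Primer]:
        return [p for p in self.primers if p.role == "species_specific"]

    def species_band(self, species: str) -> int:
        return self.expected_bands[species][0]


# ---------------------------------------------------------------------------
# species-specific primer


def _consensus_row(alignment: Alignment, species: str) -> str:
    collapsed = species_consensus(alignment, species)
    return next(r.residues for r in collapsed.rows if r.species == species)


def _footprint_columns(consensus: str, end_col: int, length: int) -> list[int] | None:
    """1-based columns of the ``length`` 3'-terminal residues ending at end_col.

    Walks left from ``end_col`` skipping gap columns of the consensus.
    Returns None when the alignment start is reached first.
    """
    cols: list[int] = []
    col = end_col
    while col >= 1 and len(cols) < length:
        if consensus[col - 1] != GAP:
            cols.append(col)
        col -= 1
    if len(cols) < length:
        return None
    return cols[::-1]


def design_species_primer(
    alignment: Alignment,
    motif: DiagnosticMotif,
    constraints: DesignConstraints | None = None,
) -> Primer:
    """Forward primer on the target consensus, 3' terminus on ``motif.end``.

    The shortest length within ``len_range`` whose Wallace Tm falls in
    ``tm_range`` wins; if none qualifies, the length minimising the distance
    to the Tm window is used.  Candidate sequences containing IUPAC
    ambiguity (unresolved within-species polymorphism) are disqualified.
    """
    constraints = constraints or DesignConstraints()
    if motif.target_allele[-1] == GAP:
        raise NoPrimerError(
            f"motif {motif.start}-{motif.end} ends on a gap; cannot anchor a 3' terminus"
        )
    consensus = _consensus_row(alignment, motif.target_species)
    lo, hi = constraints.len_range
    candidates: list[tuple[int, str, list[int]]] = []
    for length in range(lo, hi + 1):
        cols = _footprint_columns(consensus, motif.end, length)
        if cols is None:
            break  # longer lengths cannot fit either
        seq = "".join(consensus[c - 1] for c in cols)
        if set(seq) - _UNAMBIG:
            continue
        candidates.append((length, seq, cols))
    if not candidates:
        raise NoPrimerError(
            f"no unambiguous primer of length >= {lo} fits upstream of column {motif.end}"
        )

    def tm_violation(seq: str) -> float:
        tm = wallace_tm(seq)
        lo_t, hi_t = constraints.tm_range
        return max(0.0, lo_t - tm, tm - hi_t)

    in_window = [c for c in candidates if tm_violation(c[1]) == 0.0]
    length, seq, cols = (
        in_window[0] if in_window else min(candidates, key=lambda c: tm_violation(c[1]))
    )

    warnings: list[str] = []
    target_rows = [r.residues for r in alignment.rows if r.species == motif.target_species]
    poly = sum(1 for c in cols if len({row[c - 1] for row in target_rows}) > 1)
    if poly:
        warnings.append(
            f"{poly} footprint column(s) polymorphic within {motif.target_species}; "
            "primer uses the consensus state"
        )
    gc = gc_percent(seq)
    if not constraints.gc_range[0] <= gc <= constraints.gc_range[1]:
        warnings.append(f"GC {gc:.1f}% outside {constraints.gc_range}")
    tag = motif.target_species.replace(" ", "_")
    return Primer(
        name=f"{tag}-F{motif.end}",
        sequence=seq,
        orientation="forward",
        role="species_specific",
        target_species=motif.target_species,
        specific_3prime_len=motif.width,
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# universal control pair


def _conserved_runs(alignment: Alignment, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of columns where every row shares one unambiguous base."""
    runs: list[tuple[int, int]] = []
    start = None
    for col in range(1, alignment.length + 1):
        states = set(alignment.column(col))
        conserved = len(states) == 1 and next(iter(states)) in _UNAMBIG
        if conserved and start is None:
            start = col
        elif not conserved and start is not None:
            if col - start >= min_len:
                runs.append((start, col - 1))
            start = None
    if start is not None and alignment.length - start + 1 >= min_len:
        runs.append((start, alignment.length))
    return runs


def _select_length(window_seq: str, constraints: DesignConstraints, anchor: str) -> str:
    """Choose a primer inside a conserved window (anchor='left'|'right')."""
    lo, hi = constraints.len_range

    def tm_violation(seq: str) -> float:
        tm = wallace_tm(seq)
        lo_t, hi_t = constraints.tm_range
        return max(0.0, lo_t - tm, tm - hi_t)

    candidates = []
    for length in range(lo, min(hi, len(window_seq)) + 1):
        seq = window_seq[:length] if anchor == "left" else window_seq[-length:]
        candidates.append(seq)
    if not candidates:
        raise NoPrimerError("conserved window shorter than the minimum primer length")
    in_window = [s for s in candidates if tm_violation(s) == 0.0]
    return in_window[0] if in_window else min(candidates, key=tm_violation)


def design_control_pair(
    alignment: Alignment,
    constraints: DesignConstraints | None = None,
    bracket: tuple[int, int] | None = None,
) -> tuple[Primer, Primer]:
    """Universal forward/reverse pair from fully conserved windows.

    The forward primer starts at the leftmost conserved window, the reverse
    primer ends at the rightmost one, so the control amplicon brackets the
    variable region; with ``bracket`` (alignment columns) given, windows are
    required to lie strictly outside it.  The reverse primer is the reverse
    complement of its plus-strand window.
    """
    constraints = constraints or DesignConstraints()
    runs = _conserved_runs(alignment, constraints.len_range[0])
    if bracket is not None:
        left_runs = [r for r in runs if r[1] < bracket[0]]
        right_runs = [r for r in runs if r[0] > bracket[1]]
    else:
        left_runs, right_runs = runs[:1], runs[-1:]
    if not left_runs or not right_runs or left_runs[0] == right_runs[-1]:
        raise NoPrimerError(
            "no pair of conserved windows brackets the variable region"
        )
    fwd_run = left_runs[0]
    rev_run = right_runs[-1]
    row0 = alignment.rows[0].residues
    fwd_window = row0[fwd_run[0] - 1 : fwd_run[1]]
    rev_window = row0[rev_run[0] - 1 : rev_run[1]]
    fwd_seq = _select_length(fwd_window, constraints, anchor="left")
    rev_plus = _select_length(rev_window, constraints, anchor="right")
    fwd = Primer(
        name=f"ctrl-F{fwd_run[0]}",
        sequence=fwd_seq,
        orientation="forward",
        role="universal_forward",
    )
    rev = Primer(
        name=f"ctrl-R{rev_run[1]}",
        sequence=reverse_complement(rev_plus),
        orientation="reverse",
        role="universal_reverse",
    )
    return fwd, rev


def published_its2_panel() -> "PrimerPanel":
    """The published pentaplex ITS2 panel for the three Krai-Krue species.

    Three allele-specific forward primers (expected products 123/191/265 bp
    for A. pothieri / A. pierrei / A. tagala) plus the universal
    internal-control pair ITS-Aris-390F / ITS4 (400 bp).  Primer sequences
    and band sizes are the published assay's; templates must be supplied by
    the user (e.g. via scripts/fetch_accessions.py).
    """
    from importlib import resources

    from .io import read_primer_panel

    data = resources.files("barcodiag.data")
    with resources.as_file(data / "published_its2_panel.json") as p:
        return read_primer_panel(p)


# ---------------------------------------------------------------------------
# panel compatibility


def three_prime_overlap(p: str, q: str) -> int:
    """Longest k with the last k bases of ``p`` reverse-complementary to the
    last k bases of ``q`` (the 3'-dimer annealing length)."""
    kmax = min(len(p), len(q))
    best = 0
    for k in range(1, kmax + 1):
        if p[-k:] == reverse_complement(q[-k:]):
            best = k
    return best


@dataclass
class PanelReport:
    """Outcome of :func:`panel_check`; report-only, never raises."""

    separations: list[tuple[str, str, int, bool]]  # label_a, label_b, gap, ok
    cross_dimers: list[tuple[str, str, int, bool]]  # name_a, name_b, overlap, ok
    tm_spread: float
    passes: bool = field(init=False)

    def __post_init__(self):
        self.passes = all(ok for *_, ok in self.separations) and all(
            ok for *_, ok in self.cross_dimers
        )


def panel_check(panel: PrimerPanel, constraints: DesignConstraints | None = None) -> PanelReport:
    """Vet a multiplex panel: band separations, 3' cross-dimers, Tm spread.

    Bands (species bands plus the control band) must be pairwise separated
    by at least ``min_band_separation``; a 3'-terminal reverse-complement
    overlap of length >= ``max_3prime_cross_complement`` between any two
    primers (self-pairs included) fails the dimer check.
    """
    constraints = constraints or DesignConstraints()
    bands = [("control", panel.control_band)] + [
        (sp, b) for sp, sizes in panel.expected_bands.items() for b in sizes
    ]
    separations = []
    for (la, a), (lb, b) in itertools.combinations(bands, 2):
        gap = abs(a - b)
        separations.append((la, lb, gap, gap >= constraints.min_band_separation))
    cross = []
    for pa, pb in itertools.combinations_with_replacement(panel.primers, 2):
        k = three_prime_overlap(pa.sequence, pb.sequence)
        cross.append((pa.name, pb.name, k, k < constraints.max_3prime_cross_complement))
    tms = [p.tm_wallace for p in panel.primers]
    return PanelReport(
        separations=separations,
        cross_dimers=cross,
        tm_spread=max(tms) - min(tms) if tms else 0.0,
    )


# ---------------------------------------------------------------------------
# whole-panel orchestration


def _template_position(consensus: str, col: int) -> int:
    """Ungapped (template) position of an alignment column in one row."""
    return sum(1 for ch in consensus[:col] if ch != GAP)


def design_panel(
    alignment: Alignment,
    targets: list[str] | None = None,
    constraints: DesignConstraints | None = None,
    max_combinations: int = 2000,
) -> PrimerPanel:
    """Design a full multiplex panel for ``targets`` (default: all species).

    For every target species each 3'-anchorable diagnostic motif yields a
    candidate primer with a predicted band size (distance from the primer's
    5' end to the 3' end of the control amplicon on the species consensus
    template); the combination of one candidate per species maximising the
    smallest pairwise band separation wins.
    """
    from .diagnostics import diagnostic_report

    constraints = constraints or DesignConstraints()
    report = diagnostic_report(alignment)
    targets = targets or [sp for sp, entry in report.items() if entry["assayable"]]
    missing = [sp for sp in targets if not report.get(sp, {}).get("motifs")]
    if missing:
        raise NoPrimerError(f"no diagnostic motif for species: {', '.join(missing)}")

    anchorable = {
        sp: [m for m in report[sp]["motifs"] if m.target_allele[-1] != GAP]
        for sp in targets
    }
    span = (
        min(m.start for ms in anchorable.values() for m in ms),
        max(m.end for ms in anchorable.values() for m in ms),
    )
    fwd, rev = design_control_pair(alignment, constraints, bracket=span)
    # locate control footprints on alignment columns (conserved => identical rows)
    row0 = alignment.rows[0].residues
    fwd_start_col = row0.find(fwd.sequence) + 1
    rev_end_col = row0.rfind(reverse_complement(rev.sequence)) + len(rev.sequence)

    candidates: dict[str, list[tuple[Primer, int]]] = {}
    for sp in targets:
        consensus = _consensus_row(alignment, sp)
        rev_end_t = _template_position(consensus, rev_end_col)
        cands: list[tuple[Primer, int]] = []
        for motif in anchorable[sp]:
            if not (fwd_start_col < motif.start and motif.end < rev_end_col):
                continue
            try:
                primer = design_species_primer(alignment, motif, constraints)
            except NoPrimerError:
                continue
            cols = _footprint_columns(consensus, motif.end, len(primer))
            assert cols is not None
            band = rev_end_t - _template_position(consensus, cols[0]) + 1
            cands.append((primer, band))
        if not cands:
            raise NoPrimerError(f"no designable primer for species {sp!r}")
        candidates[sp] = cands

    # control band from the first target's consensus (conserved anchors =>
    # identical in every species without indels between the anchors)
    consensus0 = _consensus_row(alignment, targets[0])
    control_band = (
        _template_position(consensus0, rev_end_col)
        - _template_position(consensus0, fwd_start_col)
        + 1
    )

    species = list(candidates)
    pools = [candidates[sp] for sp in species]
    n_comb = 1
    for pool in pools:
        n_comb *= len(pool)

    def min_sep(choice: tuple[tuple[Primer, int], ...]) -> int:
        sizes = [band for _, band in choice] + [control_band]
        return min(
            abs(a - b) for a, b in itertools.combinations(sizes, 2)
        ) if len(sizes) > 1 else 10**9

    if n_comb <= max_combinations:
        best = max(itertools.product(*pools), key=min_sep)
    else:  # greedy fallback for very motif-rich panels
        chosen: list[tuple[Primer, int]] = []
        taken = [control_band]
        for pool in pools:
            pick = max(pool, key=lambda c: min(abs(c[1] - t) for t in taken))
            chosen.append(pick)
            taken.append(pick[1])
        best = tuple(chosen)

    primers = [fwd] + [p for p, _ in best] + [rev]
    expected = {sp: [band] for sp, (_, band) in zip(species, best)}
    return PrimerPanel(primers=primers, expected_bands=expected, control_band=control_band)
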