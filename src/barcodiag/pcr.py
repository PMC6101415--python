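"""In-silico multiplex PCR, virtual gel rendering and band-pattern calling.

The binding model is ARMS-style: a primer anneals where its Hamming
mismatch count is within ``max_total_mismatches`` AND its 3'-terminal
``seed_3prime_len`` bases match the template exactly — allele-specific
discrimination lives entirely in that 3' seed, matching how a single
3'-terminal mismatch blocks Taq extension.  Template IUPAC ambiguity codes
match a primer base whenever their base set contains it.

The readout is qualitative, like an ethidium-stained agarose gel: bands are
present/absent, identical predicted sizes collapse into one band, and no
intensity is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ContractError
from .records import GAP, IUPAC_SETS, SeqRecord, reverse_complement
from .primers import Primer, PrimerPanel

NON_TARGET = "NON_TARGET"
NO_AMPLIFICATION = "NO_AMPLIFICATION"
AMBIGUOUS_MIXTURE = "AMBIGUOUS_MIXTURE"


@dataclass(frozen=True)
class MismatchModel:
    """Annealing tolerance of the virtual polymerase."""

    max_total_mismatches: int = 2
    seed_3prime_len: int = 4
    max_amplicon_len: int = 2000

    def __post_init__(self):
        if self.max_total_mismatches < 0 or self.seed_3prime_len < 0:
            raise ContractError("negative mismatch-model parameter")
        if self.max_amplicon_len < 1:
            raise ContractError("max_amplicon_len must be >= 1")


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    primer_name: str
    strand: str  # "plus" (primes rightward) | "minus" (primes leftward)
    start: int  # 1-based inclusive footprint on the plus strand
    end: int
    mismatches: int
    three_prime_ok: bool = True


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    forward_primer: str
    reverse_primer: str
    start: int
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GelLane:
    sample_id: str
    bands: tuple[int, ...]  # descending, duplicates collapsed
    migrations: tuple[float, ...] | None = None


@dataclass(frozen=True)
class SpeciesCall:
    sample_id: str
    call: str  # species name | NON_TARGET | NO_AMPLIFICATION | AMBIGUOUS_MIXTURE
    bands: tuple[int, ...]
    evidence: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# binding


_BASE_ORD = {b: 1 << i for i, b in enumerate("ACGT")}
_CODE_MASK = np.zeros(128, dtype=np.uint8)
for _code, _bases in IUPAC_SETS.items():
    _CODE_MASK[ord(_code)] = sum(_BASE_ORD[b] for b in _bases)


def _mask_array(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_MASK[arr]


def _scan(template_mask: np.ndarray, primer_mask: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer at every template offset (sliding)."""
    L = primer_mask.shape[0]
    n = template_mask.shape[0]
    if n < L:
        return np.empty((0,), dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(template_mask, L)
    # a primer base matches iff the template's IUPAC set contains it
    matches = (windows & primer_mask) == primer_mask
    return L - matches.sum(axis=1)


def find_binding_sites(
    template: SeqRecord, primer: Primer, model: MismatchModel | None = None
) -> list[BindingSite]:
    """All annealing sites of a primer on both strands of a linear template.

    Plus-strand sites (primer sequence matches the plus strand) prime
    rightward synthesis; minus-strand sites (reverse complement of the
    primer matches the plus strand) prime leftward.
    """
    model = model or MismatchModel()
    if GAP in template.residues:
        raise ContractError(f"template {template.id!r} contains gaps; ungap it first")
    seed = min(model.seed_3prime_len, len(primer))
    tmpl_mask = _mask_array(template.residues)
    sites: list[BindingSite] = []
    L = len(primer)

    pm = _mask_array(primer.sequence)
    mism = _scan(tmpl_mask, pm)
    if seed:
        seed_mism = _scan(tmpl_mask, pm[-seed:])
    for off in np.nonzero(mism <= model.max_total_mismatches)[0]:
        if seed and seed_mism[off + L - seed] != 0:
            continue
        sites.append(
            BindingSite(
                template_id=template.id,
                primer_name=primer.name,
                strand="plus",
                start=int(off) + 1,
                end=int(off) + L,
                mismatches=int(mism[off]),
            )
        )

    rc = _mask_array(reverse_complement(primer.sequence))
    mism_rc = _scan(tmpl_mask, rc)
    if seed:
        seed_mism_rc = _scan(tmpl_mask, rc[:seed])
    for off in np.nonzero(mism_rc <= model.max_total_mismatches)[0]:
        if seed and seed_mism_rc[off] != 0:
            continue
        sites.append(
            BindingSite(
                template_id=template.id,
                primer_name=primer.name,
                strand="minus",
                start=int(off) + 1,
                end=int(off) + L,
                mismatches=int(mism_rc[off]),
            )
        )
    sites.sort(key=lambda s: (s.start, s.strand, s.primer_name))
    return sites


# ---------------------------------------------------------------------------
# multiplex PCR


def amplify(
    primers: Sequence[Primer], template: SeqRecord, model: MismatchModel | None = None
) -> list[Amplicon]:
    """All products of a primer set on one template.

    Every (rightward site, leftward site) pair with the rightward footprint
    entirely 5' of the leftward footprint and span within
    ``max_amplicon_len`` yields an amplicon; length = end - start + 1.
    """
    model = model or MismatchModel()
    fwd_sites: list[BindingSite] = []
    rev_sites: list[BindingSite] = []
    for primer in primers:
        for site in find_binding_sites(template, primer, model):
            (fwd_sites if site.strand == "plus" else rev_sites).append(site)
    out: list[Amplicon] = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.end < r.start and (r.end - f.start + 1) <= model.max_amplicon_len:
                out.append(
                    Amplicon(
                        template_id=template.id,
                        forward_primer=f.primer_name,
                        reverse_primer=r.primer_name,
                        start=f.start,
                        end=r.end,
                    )
                )
    out.sort(key=lambda a: (a.start, a.end, a.forward_primer))
    return out


def lane_from_amplicons(sample_id: str, amplicons: Iterable[Amplicon]) -> GelLane:
    """Collapse amplicon sizes into a descending band multiset (gel view)."""
    sizes = sorted({a.length_bp for a in amplicons}, reverse=True)
    return GelLane(sample_id=sample_id, bands=tuple(sizes))


def multiplex_pcr(
    panel: PrimerPanel,
    templates: Iterable[SeqRecord],
    model: MismatchModel | None = None,
) -> dict[str, tuple[list[Amplicon], GelLane]]:
    """Run the whole panel on every template; one lane per template."""
    model = model or MismatchModel()
    out: dict[str, tuple[list[Amplicon], GelLane]] = {}
    for template in templates:
        amps = amplify(panel.primers, template, model)
        out[template.id] = (amps, lane_from_amplicons(template.id, amps))
    return out


def pool_lanes(sample_id: str, lanes: Iterable[GelLane]) -> GelLane:
    """One lane for a pooled sample (e.g. mixed genomic DNA): the union of
    the component band patterns, duplicates collapsed."""
    sizes = sorted({b for lane in lanes for b in lane.bands}, reverse=True)
    return GelLane(sample_id=sample_id, bands=tuple(sizes))


# ---------------------------------------------------------------------------
# calling


def _match_band(observed: Sequence[int], expected: int, tol: float) -> int | None:
    """Closest observed band within relative tolerance of ``expected``."""
    hits = [b for b in observed if abs(b - expected) <= tol * expected]
    return min(hits, key=lambda b: abs(b - expected)) if hits else None


def call_species(
    lane: GelLane, panel: PrimerPanel, size_tolerance: float = 0.10
) -> SpeciesCall:
    """Turn a band pattern into a species call.

    Control band present and exactly one species band -> that species;
    control only -> NON_TARGET; no control -> NO_AMPLIFICATION; control plus
    two or more species bands -> AMBIGUOUS_MIXTURE.  Matching is within a
    relative ``size_tolerance``; band order is irrelevant.
    """
    evidence: list[str] = []
    control = _match_band(lane.bands, panel.control_band, size_tolerance)
    if control is None:
        return SpeciesCall(lane.sample_id, NO_AMPLIFICATION, lane.bands)
    evidence.append(f"control {panel.control_band} bp matched by {control} bp")
    non_control = [b for b in lane.bands if b != control]
    matched: list[str] = []
    for species, bands in panel.expected_bands.items():
        hits = [_match_band(non_control, b, size_tolerance) for b in bands]
        if all(h is not None for h in hits):
            matched.append(species)
            evidence.append(
                f"{species}: expected {bands} matched by {[int(h) for h in hits]}"
            )
    if len(matched) == 1:
        return SpeciesCall(lane.sample_id, matched[0], lane.bands, tuple(evidence))
    if len(matched) == 0:
        return SpeciesCall(lane.sample_id, NON_TARGET, lane.bands, tuple(evidence))
    return SpeciesCall(lane.sample_id, AMBIGUOUS_MIXTURE, lane.bands, tuple(evidence))


# ---------------------------------------------------------------------------
# virtual gel


def gel_migration(length_bp: int, gel: tuple[float, float] = (100.0, 30.0)) -> float:
    """Migration distance a - b*log10(length); strictly decreasing in length."""
    if length_bp < 1:
        raise ContractError("length_bp must be >= 1")
    a, b = gel
    return a - b * math.log10(length_bp)


DEFAULT_LADDER = (1000, 750, 500, 400, 300, 200, 150, 100, 50)


def render_gel_ascii(
    lanes: Sequence[GelLane],
    ladder: Sequence[int] = DEFAULT_LADDER,
    gel: tuple[float, float] = (100.0, 30.0),
    height: int = 24,
) -> str:
    """ASCII rendering of a virtual agarose gel with a size ladder."""
    all_lanes = [GelLane("ladder", tuple(sorted(ladder, reverse=True)))] + list(lanes)
    sizes = [b for lane in all_lanes for b in lane.bands]
    if not sizes:
        return "(empty gel)\n"
    migrations = {b: gel_migration(b, gel) for b in set(sizes)}
    mmin = min(migrations.values())
    mmax = max(migrations.values())
    span = (mmax - mmin) or 1.0
    width = max(8, max(len(l.sample_id) for l in all_lanes) + 2)
    rows = [[" " * width for _ in all_lanes] for _ in range(height)]
    for j, lane in enumerate(all_lanes):
        for b in lane.bands:
            r = round((migrations[b] - mmin) / span * (height - 1))
            label = f"{b}".center(width - 2)
            rows[r][j] = f"[{label}]" if j == 0 else f" {'=' * (width - 2)} "
    header = "".join(l.sample_id.center(width) for l in all_lanes)
    body = "\n".join("".join(row) for row in rows)
    return header + "\n" + body + "\n"
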