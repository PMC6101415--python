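"""Synthetic species panels with planted, known-truth structure.

The generator emulates the anatomy of a spacer-locus barcode panel: one
ancestral sequence per locus; species-private fixed motifs (substitutions
or deletions) planted at chosen positions — the ground truth diagnostic
sites; background interspecific divergence outside the planted regions;
fully conserved blocks that serve as universal primer anchors; and
per-individual intraspecific noise.

Truth guarantees, by construction:

* planted motifs are exactly the species-diagnostic columns whenever
  ``intra_rate`` is 0 — background substitutions are assigned to subsets of
  2..(n_species-2) species so they are never private to one species nor to
  the complement (hence ``n_species >= 4`` whenever background divergence
  is requested);
* neither background divergence nor intraspecific noise ever touches
  conserved blocks or planted motif columns;
* everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np

from .errors import ParameterError
from .records import GAP, Alignment, SeqRecord, SpeciesPanel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedMotif:
    """One species-private feature planted into the ancestral sequence."""

    species: str
    start: int  # 1-based ancestral (= alignment) column
    width: int
    kind: str  # "substitution" | "deletion"
    allele: str | None = None  # filled in by the generator for substitutions

    @property
    def end(self) -> int:
        return self.start + self.width - 1


@dataclass
class FixtureParams:
    """Study conditions for one synthetic panel."""

    n_species: int = 4
    per_species: int = 3
    locus_len: int = 400
    diag_spec: list[PlantedMotif] = field(default_factory=list)
    intra_rate: float = 0.0
    interspecies_rate: float = 0.02
    conserved_blocks: list[tuple[int, int]] = field(default_factory=list)
    species_names: list[str] | None = None
    locus: str = "ITS2-like"
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2 or self.per_species < 1:
            raise ParameterError("need >= 2 species and >= 1 individual each")
        if not (0 <= self.intra_rate < 1 and 0 <= self.interspecies_rate < 1):
            raise ParameterError("rates must lie in [0, 1)")
        if self.interspecies_rate > 0 and self.n_species < 4:
            raise ParameterError(
                "background divergence needs n_species >= 4 to stay non-diagnostic"
            )
        names = self.names()
        if len(names) != self.n_species:
            raise ParameterError("species_names length != n_species")
        occupied: set[int] = set()
        for s, e in self.conserved_blocks:
            if not (1 <= s <= e <= self.locus_len):
                raise ParameterError(f"conserved block {s}-{e} outside locus")
            occupied |= set(range(s, e + 1))
        for m in self.diag_spec:
            if m.species not in names:
                raise ParameterError(f"motif for unknown species {m.species!r}")
            if not (1 <= m.start <= m.end <= self.locus_len):
                raise ParameterError(f"motif {m.start}-{m.end} outside locus")
            if m.kind not in ("substitution", "deletion"):
                raise ParameterError(f"unknown motif kind {m.kind!r}")
            cols = set(range(m.start, m.end + 1))
            if cols & occupied:
                raise ParameterError(
                    f"motif {m.start}-{m.end} overlaps a conserved block or another motif"
                )
            occupied |= cols

    def names(self) -> list[str]:
        if self.species_names is not None:
            return list(self.species_names)
        return [f"species_{i + 1:02d}" for i in range(self.n_species)]


@dataclass
class FixtureTruth:
    """What was planted; the oracle for every downstream module."""

    seed: int
    species: list[str]
    planted_motifs: list[PlantedMotif]
    background_columns: list[int]
    conserved_blocks: list[tuple[int, int]]
    individuals: dict[str, str]  # record id -> species
    intra_rate: float
    interspecies_rate: float

    def motifs_for(self, species: str) -> list[PlantedMotif]:
        return [m for m in self.planted_motifs if m.species == species]

    def to_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureTruth":
        doc = json.loads(text)
        doc["planted_motifs"] = [PlantedMotif(**m) for m in doc["planted_motifs"]]
        doc["conserved_blocks"] = [tuple(b) for b in doc["conserved_blocks"]]
        return cls(**doc)


def _random_base_not(rng: np.random.Generator, current: int) -> int:
    """A random base code different from ``current``."""
    choices = _BASES[_BASES != current]
    return int(choices[rng.integers(0, len(choices))])


def simulate_panel(
    params: FixtureParams,
) -> tuple[SpeciesPanel, Alignment, FixtureTruth]:
    """Generate a panel, its true alignment, and the planted-feature truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    names = params.names()
    L = params.locus_len

    ancestor = _BASES[rng.integers(0, 4, size=L)].copy()

    protected = np.zeros(L, dtype=bool)  # conserved blocks + motif columns
    for s, e in params.conserved_blocks:
        protected[s - 1 : e] = True
    for m in params.diag_spec:
        protected[m.start - 1 : m.end] = True

    # background divergence: shared-subset substitutions, never private
    background_cols: list[int] = []
    species_cols: dict[str, dict[int, int]] = {sp: {} for sp in names}
    if params.interspecies_rate > 0:
        eligible = np.nonzero(~protected)[0]
        hit = eligible[rng.random(len(eligible)) < params.interspecies_rate]
        for col in hit:
            k = int(rng.integers(2, params.n_species - 1))  # 2..n-2 inclusive
            subset = rng.choice(params.n_species, size=k, replace=False)
            derived = _random_base_not(rng, int(ancestor[col]))
            for si in subset:
                species_cols[names[si]][int(col)] = derived
            background_cols.append(int(col) + 1)

    # planted motifs
    planted: list[PlantedMotif] = []
    deletions: dict[str, set[int]] = {sp: set() for sp in names}
    for m in params.diag_spec:
        if m.kind == "substitution":
            if m.allele is None:
                allele = "".join(
                    chr(_random_base_not(rng, int(ancestor[c])))
                    for c in range(m.start - 1, m.end)
                )
            else:
                allele = m.allele
            for off, ch in enumerate(allele):
                species_cols[m.species][m.start - 1 + off] = ord(ch)
            planted.append(
                PlantedMotif(m.species, m.start, m.width, m.kind, allele)
            )
        else:  # deletion
            deletions[m.species] |= set(range(m.start - 1, m.end))
            planted.append(
                PlantedMotif(m.species, m.start, m.width, m.kind, GAP * m.width)
            )

    masters: dict[str, np.ndarray] = {}
    for sp in names:
        seq = ancestor.copy()
        for col, base in species_cols[sp].items():
            seq[col] = base
        masters[sp] = seq

    # individuals with intraspecific noise outside protected columns
    noise_ok = np.nonzero(~protected)[0]
    rows: list[SeqRecord] = []
    individuals: dict[str, str] = {}
    for sp in names:
        for k in range(params.per_species):
            seq = masters[sp].copy()
            if params.intra_rate > 0:
                hit = noise_ok[rng.random(len(noise_ok)) < params.intra_rate]
                for col in hit:
                    seq[col] = _random_base_not(rng, int(seq[col]))
            chars = seq.tobytes().decode("ascii")
            residues = "".join(
                GAP if i in deletions[sp] else ch for i, ch in enumerate(chars)
            )
            rec_id = f"{sp}_{k + 1:02d}"
            rows.append(SeqRecord(rec_id, residues, species=sp, locus=params.locus))
            individuals[rec_id] = sp

    alignment = Alignment(rows)
    panel = SpeciesPanel(
        (SeqRecord(r.id, r.ungapped, r.species, r.locus) for r in rows),
        locus=params.locus,
    )
    truth = FixtureTruth(
        seed=params.seed,
        species=names,
        planted_motifs=planted,
        background_columns=sorted(background_cols),
        conserved_blocks=list(params.conserved_blocks),
        individuals=individuals,
        intra_rate=params.intra_rate,
        interspecies_rate=params.interspecies_rate,
    )
    return panel, alignment, truth


# ---------------------------------------------------------------------------
# packaged three-species demo (synthetic stand-in for a real assay panel)

DEMO_SEED = 20180823
DEMO_TARGETS = ["A_pothieri_like", "A_pierrei_like", "A_tagala_like"]
DEMO_NON_TARGET = "substitute_sp"


def demo_params(seed: int = DEMO_SEED) -> FixtureParams:
    """Study conditions of the packaged demo: three assay targets plus one
    non-target relative, universal anchors bracketing a variable spacer,
    species-private motifs of width 2/1/4 and one private deletion."""
    names = DEMO_TARGETS + [DEMO_NON_TARGET]
    return FixtureParams(
        n_species=4,
        per_species=3,
        locus_len=520,
        species_names=names,
        conserved_blocks=[(61, 100), (441, 460)],
        diag_spec=[
            PlantedMotif("A_pothieri_like", 356, 2, "substitution"),
            PlantedMotif("A_pierrei_like", 289, 1, "substitution"),
            PlantedMotif("A_tagala_like", 212, 4, "substitution"),
            PlantedMotif("A_pothieri_like", 30, 6, "deletion"),
        ],
        intra_rate=0.0,
        interspecies_rate=0.05,
        locus="ITS2-like",
        seed=seed,
    )


def build_krai_krue_demo(seed: int = DEMO_SEED):
    """Generate the demo panel and design its multiplex primer panel.

    Returns (panel, alignment, truth, primer_panel).  Used once to produce
    the committed demo data; tests and :func:`krai_krue_demo` read the
    committed copy.
    """
    from .primers import design_panel

    panel, alignment, truth = simulate_panel(demo_params(seed))
    primer_panel = design_panel(alignment, targets=DEMO_TARGETS)
    return panel, alignment, truth, primer_panel


def krai_krue_demo():
    """The packaged synthetic three-species assay demo.

    Returns (panel, alignment, truth, primer_panel) loaded from the data
    files committed with the package (generating seed recorded in the truth
    table).  Sequences are synthetic; only the panel *structure* mirrors a
    real crude-drug discrimination assay.
    """
    from .io import read_primer_panel
    from . import io as _io

    data = resources.files("barcodiag.data")
    with resources.as_file(data / "krai_krue_demo_aligned.fasta") as p:
        alignment = _io.read_alignment(p, "fasta")
    panel = SpeciesPanel(
        (SeqRecord(r.id, r.ungapped, r.species, r.locus) for r in alignment.rows),
        locus="ITS2-like",
    )
    truth = FixtureTruth.from_json((data / "krai_krue_demo_truth.json").read_text())
    with resources.as_file(data / "krai_krue_demo_panel.json") as p:
        primer_panel = read_primer_panel(p)
    return panel, alignment, truth, primer_panel
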