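"""Diagnostic site detection vs an exhaustive column-scan oracle, motif
merging, and consensus collapsing."""

import numpy as np
import pytest

from barcodiag.diagnostics import (
    DiagnosticMotif,
    diagnostic_report,
    find_diagnostic_sites,
    merge_adjacent,
    species_consensus,
)
from barcodiag.errors import ContractError, InsufficientDataError, UnknownSpeciesError
from barcodiag.records import IUPAC_SETS, Alignment, SeqRecord
from barcodiag.simulate import FixtureParams, PlantedMotif, simulate_panel

from conftest import make_alignment


def oracle_sites(alignment, target):
    """Independent re-implementation: literal set comparison per column.

    A column is diagnostic iff all target rows carry one state in ACGT-,
    and no non-target row carries that state nor an ambiguity containing it.
    """
    out = []
    tgt = [r.residues for r in alignment.rows if r.species == target]
    oth = [r.residues for r in alignment.rows if r.species != target]
    for col in range(alignment.length):
        states = {row[col] for row in tgt}
        if len(states) != 1:
            continue
        (s,) = states
        if s not in "ACGT-":
            continue
        blocked = False
        for row in oth:
            ch = row[col]
            if ch == s or s in IUPAC_SETS.get(ch, frozenset()):
                blocked = True
                break
        if not blocked:
            out.append((col + 1, s))
    return out


def test_simple_fixed_difference_is_found():
    rows = {
        "a1": "ACGTTCGG",
        "a2": "ACGTTCGG",
        "b1": "ACGTCCGG",
        "b2": "ACGTCCGG",
        "c1": "ACGTCCGG",
    }
    species = {k: k[0] for k in rows}
    aln = make_alignment(rows, species)
    sites = find_diagnostic_sites(aln, "a")
    assert [(m.start, m.target_allele) for m in sites] == [(5, "T")]
    assert sites[0].background_alleles == frozenset("C")


def test_unfixed_target_column_is_not_diagnostic():
    aln = make_alignment(
        {"a1": "ACT", "a2": "ACC", "b1": "ACC", "b2": "ACC"},
        {"a1": "a", "a2": "a", "b1": "b", "b2": "b"},
    )
    assert find_diagnostic_sites(aln, "a") == []


def test_nontarget_ambiguity_blocks_diagnosis():
    # non-target R = {A,G} contains the candidate G -> blocked
    aln = make_alignment(
        {"a1": "G", "b1": "R", "c1": "C"}, {"a1": "a", "b1": "b", "c1": "c"}
    )
    assert find_diagnostic_sites(aln, "a") == []
    # Y = {C,T} does not contain G -> diagnostic
    aln2 = make_alignment(
        {"a1": "G", "b1": "Y", "c1": "C"}, {"a1": "a", "b1": "b", "c1": "c"}
    )
    assert [(m.start, m.target_allele) for m in find_diagnostic_sites(aln2, "a")] == [
        (1, "G")
    ]


def test_gap_is_a_legal_diagnostic_state():
    aln = make_alignment(
        {"a1": "AC-T", "a2": "AC-T", "b1": "ACGT", "c1": "ACGT"},
        {"a1": "a", "a2": "a", "b1": "b", "c1": "c"},
    )
    assert [(m.start, m.target_allele) for m in find_diagnostic_sites(aln, "a")] == [
        (3, "-")
    ]


@pytest.mark.parametrize("seed", range(10))
def test_matches_exhaustive_oracle_on_random_alignments(seed):
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT-RN"))
    n_species, per, L = 4, 2, 40
    rows, species = {}, {}
    for s in range(n_species):
        for k in range(per):
            rid = f"s{s}_{k}"
            rows[rid] = "".join(rng.choice(alphabet, L, p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.03, 0.03]))
            species[rid] = f"sp{s}"
    aln = make_alignment(rows, species)
    for target in [f"sp{s}" for s in range(n_species)]:
        got = [(m.start, m.target_allele) for m in find_diagnostic_sites(aln, target)]
        assert got == oracle_sites(aln, target)


def test_unknown_species_raises():
    aln = make_alignment({"a1": "A", "b1": "C"}, {"a1": "a", "b1": "b"})
    with pytest.raises(UnknownSpeciesError):
        find_diagnostic_sites(aln, "nope")


def _site(col, allele="T", sp="x"):
    return DiagnosticMotif(sp, col, col, allele)


def test_merge_adjacent_runs():
    merged = merge_adjacent([_site(560), _site(561)])
    assert [(m.start, m.end, m.target_allele) for m in merged] == [(560, 561, "TT")]
    assert [(m.start, m.end) for m in merge_adjacent([_site(5), _site(7)])] == [
        (5, 5),
        (7, 7),
    ]
    assert merge_adjacent([]) == []


def test_merge_adjacent_rejects_mixed_species():
    with pytest.raises(ContractError):
        merge_adjacent([_site(1, sp="x"), _site(2, sp="y")])


def test_report_recovers_planted_motifs_with_no_false_positives():
    """On noise-free fixtures, recall of planted motifs is 1.0 and the
    false-discovery count is 0, across many seeded replicates."""
    for seed in range(20):
        params = FixtureParams(
            n_species=4,
            per_species=2,
            locus_len=150,
            seed=seed,
            diag_spec=[
                PlantedMotif("species_01", 40, 2, "substitution"),
                PlantedMotif("species_02", 70, 1, "substitution"),
                PlantedMotif("species_03", 100, 3, "deletion"),
            ],
            intra_rate=0.0,
            interspecies_rate=0.04,
        )
        _, aln, truth = simulate_panel(params)
        report = diagnostic_report(aln)
        for sp in truth.species:
            got = {(m.start, m.end, m.target_allele) for m in report[sp]["motifs"]}
            want = {(m.start, m.end, m.allele) for m in truth.motifs_for(sp)}
            assert got == want, f"seed {seed}, species {sp}"


def test_report_flags_and_degenerate_inputs():
    # two identical species: no motifs, not assayable
    aln = make_alignment(
        {"a1": "ACGT", "b1": "ACGT"}, {"a1": "a", "b1": "b"}
    )
    rep = diagnostic_report(aln)
    assert all(not e["motifs"] and not e["assayable"] for e in rep.values())
    # single species: insufficient
    single = make_alignment({"a1": "ACGT", "a2": "ACGT"}, {"a1": "a", "a2": "a"})
    with pytest.raises(InsufficientDataError):
        diagnostic_report(single)


def test_output_invariant_under_row_permutation_and_duplication():
    rows = {
        "a1": "ACGTTCGG",
        "a2": "ACGTTCGG",
        "b1": "ACTTCCGG",
        "c1": "AGGTCCGG",
    }
    species = {k: k[0] for k in rows}
    base = find_diagnostic_sites(make_alignment(rows, species), "a")
    shuffled = make_alignment(dict(reversed(rows.items())), species)
    dup_rows = rows | {"a3": rows["a1"]}
    dup = make_alignment(dup_rows, species | {"a3": "a"})
    key = [(m.start, m.target_allele) for m in base]
    assert [(m.start, m.target_allele) for m in find_diagnostic_sites(shuffled, "a")] == key
    assert [(m.start, m.target_allele) for m in find_diagnostic_sites(dup, "a")] == key


def test_reported_motifs_self_verify(demo):
    """Every reported motif satisfies its own invariants when re-checked
    column-by-column on the packaged demo alignment."""
    _, aln, _, _ = demo
    report = diagnostic_report(aln)
    for sp, entry in report.items():
        for m in entry["motifs"]:
            for off in range(m.width):
                col = aln.column(m.start + off)
                want = m.target_allele[off]
                for r, ch in zip(aln.rows, col):
                    if r.species == sp:
                        assert ch == want
                    else:
                        assert ch != want


def test_species_consensus_majority_and_ties():
    aln = make_alignment(
        {"a1": "AAG", "a2": "AAT", "a3": "ACG", "b1": "CCC"},
        {"a1": "a", "a2": "a", "a3": "a", "b1": "b"},
    )
    collapsed = species_consensus(aln, "a")
    row = next(r for r in collapsed.rows if r.species == "a")
    # col1 unanimous A; col2 majority A; col3 majority G
    assert row.residues == "AAG"
    tie = make_alignment({"a1": "G", "a2": "T", "b1": "C"},
                         {"a1": "a", "a2": "a", "b1": "b"})
    tie_row = next(r for r in species_consensus(tie, "a").rows if r.species == "a")
    assert tie_row.residues == "K"  # G/T tie -> IUPAC K
    assert len(collapsed) == 2


def test_min_target_freq_relaxes_fixation():
    rows = {"a1": "T", "a2": "T", "a3": "C", "b1": "G"}
    species = {k: k[0] for k in rows}
    aln = make_alignment(rows, species)
    assert find_diagnostic_sites(aln, "a", min_target_freq=1.0) == []
    relaxed = find_diagnostic_sites(aln, "a", min_target_freq=0.6)
    assert [(m.start, m.target_allele) for m in relaxed] == [(1, "T")]
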