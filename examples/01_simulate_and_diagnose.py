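"""Simulate a labelled species panel and find its diagnostic motifs.

Generates a four-species panel with three planted species-private motifs
(two substitutions, one deletion), then scans the alignment for columns
fixed in one species and absent from all others.  The reported intervals
should be exactly the planted ones.
"""

from barcodiag import diagnostic_report, simulate_panel
from barcodiag.simulate import FixtureParams, PlantedMotif

params = FixtureParams(
    n_species=4,
    per_species=2,
    locus_len=150,
    seed=7,
    diag_spec=[
        PlantedMotif("species_01", 40, 2, "substitution"),
        PlantedMotif("species_02", 70, 1, "substitution"),
        PlantedMotif("species_03", 100, 3, "deletion"),
    ],
    interspecies_rate=0.04,
)
panel, alignment, truth = simulate_panel(params)

print(f"{len(panel)} individuals, {alignment.length} alignment columns")
print("planted:", [(m.species, m.start, m.end, m.allele) for m in truth.planted_motifs])

report = diagnostic_report(alignment)
for species, entry in report.items():
    motifs = [(m.start, m.end, m.target_allele) for m in entry["motifs"]]
    print(f"{species}: motifs={motifs} assayable={entry['assayable']}")

# Each motif (start, end, allele) is an alignment interval where the target
# species is fixed for an allele no other species carries -- the anchor for
# an allele-specific primer.  A '-' allele is a private deletion: real
# diagnostic signal, but unusable as a primer 3' anchor (assayable looks at
# non-gap motifs only).
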