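# Methods

This note records the models, rules and numerical choices behind
`barcodiag`, the assumptions they make, and what the packaged tests do and
do not demonstrate.

## Diagnostic characters

A column of a species-labelled alignment is *diagnostic* for species *s*
when every row of *s* carries one identical state from {A, C, G, T, −} and
that state occurs in no other row. This is strict character-based
diagnosis: it is exactly the condition under which a primer ending on the
site is perfectly matched in *s* and 3′-mismatched in everything else, so
it is the right notion for assay design, even though it is more
conservative than phylogenetic (synapomorphy-based) diagnosis. Two
deliberate conservatisms:

* A non-target IUPAC ambiguity whose base set contains the candidate
  allele *blocks* diagnosis — we refuse to anchor chemistry on an
  uncertain base call.
* Within-species polymorphism at a column removes it from consideration at
  the default `min_target_freq = 1.0`. Real panels often carry a little
  intraspecific heterogeneity (e.g. two-base differences between
  conspecific accessions); the supported route is to collapse each species
  to its majority consensus first (`species_consensus`, ties becoming
  IUPAC codes) — mirroring how published assays design on consensus
  sequences — or to relax `min_target_freq`.

Runs of adjacent diagnostic columns merge into multi-base motifs; gap
alleles are legitimate motifs (private deletions) but cannot anchor a 3′
terminus, hence the per-species `assayable` flag. Coordinates are 1-based
inclusive and always refer to the alignment actually analysed; coordinates
from someone else's alignment of the same locus are meaningless here.

## Primer design

Species primers are read off the target species' consensus, ending exactly
on the motif's 3′-most base. Length selection: the shortest length within
`len_range` (default 15–25 nt) whose Wallace Tm, 2·(A+T) + 4·(G+C) °C,
falls inside `tm_range` (default 48–62 °C, suiting a ~52 °C multiplex
annealing); if none qualifies, the length minimising the distance to the
window. The Wallace rule is crude but deterministic and adequate for
15–25-mers; a nearest-neighbor model was deliberately not adopted — it
would add thermodynamic tables without changing any downstream decision
this toolkit makes.

The control pair is drawn from fully conserved windows (every row one
unambiguous base) bracketing the species motifs, so every species amplicon
nests inside the control product and "non-target" is distinguishable from
"no template". Whole-panel assembly (`design_panel`) enumerates candidate
(motif, primer) combinations per species and picks the combination
maximising the smallest pairwise band separation (exhaustive up to 2,000
combinations, then greedy).

Panel vetting checks band separations against `min_band_separation`
(default 30 bp, comfortable for 1.5–2 % agarose), the maximal 3′-terminal
reverse-complement overlap between every primer pair (fail at ≥ 4 by
default; the 3′ end is where a dimer extends), and the panel Tm spread.
Hairpin screening is limited to self-complementary 3′ runs — a documented
simplification, not a thermodynamic fold.

## In-silico PCR and calling

A primer binds where its Hamming mismatch count is ≤ `max_total_mismatches`
(default 2) *and* its 3′-terminal `seed_3prime_len` bases (default 4) match
exactly — the ARMS assumption that extension is governed by the 3′ end.
Template IUPAC codes match a primer base iff their base set contains it.
Every (rightward, leftward) site pair with the rightward footprint entirely
5′ of the leftward one and span ≤ `max_amplicon_len` (default 2,000 bp)
becomes an amplicon; footprint-to-footprint, 1-based inclusive, so a
forward site starting at 101 and a reverse site ending at 300 give 200 bp.
Templates are linear plus-strand records; primer concentration, efficiency
and band intensity are not modelled — the readout of an ethidium-stained
gel is qualitative presence/absence, and identical predicted sizes collapse
into one band (the amplicon table keeps all products).

Calling, at a relative `size_tolerance` of 10 % (the default band layouts
are separated by far more): control band + exactly one species band → that
species; control only → `NON_TARGET`; no control → `NO_AMPLIFICATION`;
control + ≥ 2 species bands → `AMBIGUOUS_MIXTURE`. Gel rendering uses the
standard semi-log migration model `distance = a − b·log10(length)`.

## Distances and trees

K2P: `d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)` with transitions {A↔G, C↔T};
saturated pairs (a log argument ≤ 0) raise an error rather than returning a
number. Columns with a gap or ambiguity in either row of a pair are
deleted *pairwise*, not list-wise — complete deletion would discard most of
an indel-rich spacer alignment. Neighbor-joining follows Saitou–Nei with
two determinism guarantees: ties on the Q-criterion break lexicographically
on the smallest leaf label of each cluster, and negative branch lengths are
clamped to zero. Maximum-likelihood search was consciously replaced by
K2P + NJ: NJ is fully specifiable, desk-verifiable against brute-force
topology enumeration, and the coarse claims this toolkit asserts (deep
clades, monophyly of a genus against outgroups) are distance-recoverable;
fine within-genus support values are ML-sensitive and are not asserted.

Bootstrap resamples columns with replacement using
`numpy.random.default_rng(seed)` (PCG64, platform-stable), rebuilds the NJ
tree per replicate, and reports for each internal bipartition of the
full-data tree the percentage of replicates containing it. Replicates in
which some distance is undefined are dropped from the denominator (rare;
only near saturation). Monophyly of a group means some edge bipartition
equals the group exactly.

## The progressive aligner

`msa_lite` exists so small panels need no external aligner: global pairwise
alignment with affine gaps (Gotoh; a gap of length L costs
`gap_open + (L−1)·gap_extend`, defaults 1/−1/−4/−1), a UPGMA guide built on
pairwise p-distances with lexicographic tie-breaking, and profile merging
through per-profile majority-consensus strings under "once a gap, always a
gap". It targets desk-scale barcode panels (tens of records, ≤ ~5 kb) and
does not attempt to reproduce any particular aligner column-for-column;
externally produced alignments (aligned FASTA or Clustal) are first-class
inputs everywhere. The DP kernel is JIT-compiled (numba), so the first
call in a session pays a one-off compile cost.

## The synthetic generator

`simulate_panel` emulates the anatomy of a spacer-locus barcode panel: a
uniform-random ancestral sequence; species-private planted motifs
(substitutions with alleles forced off the ancestral state, or deletions);
conserved blocks exempt from all mutation (universal primer anchors);
background interspecific divergence; per-individual intraspecific noise.
Background substitutions are assigned to random subsets of 2…(n−2) species
at distinct columns, so they are never private to one species nor to the
complement — with ≥ 4 species the planted motifs are therefore *exactly*
the diagnostic columns at zero intraspecific noise, which is what makes
recall/false-discovery statements well-defined. Neither background
divergence nor noise touches conserved blocks or motif columns.

What the generator does **not** emulate: rDNA concerted evolution,
alignment uncertainty (the true alignment is known by construction),
sequencing error, heterozygous/chimeric templates, or length heteroplasmy.
Passing tests on these fixtures demonstrate the *algorithms'* correctness
under their stated models, not robustness to every artefact of real
herbarium-grade data.

The committed demo (`krai_krue_demo`, seed 20180823, regenerable via
`scripts/make_demo_data.py`) mirrors the structure of a published
three-species crude-drug assay: three targets with planted motifs of width
2/1/4, one private deletion, one related non-target species, and universal
anchors bracketing the variable region. Its sequences are synthetic; only
the panel geometry is modelled on the real assay.

## Problem sizes and reproducibility

The default test suite and `scripts/acceptance.py` use deliberately small
panels (4–6 species, 120–520-column loci, 100 simulation replicates,
1,000 bootstrap replicates) — sizes at which every oracle (exhaustive
column scans, brute-force alignment enumeration, topology enumeration) is
exact and the whole suite runs in seconds. All randomness flows from
explicit seeds; identical seeds give byte-identical outputs.

## Reproduction against deposited records

Checks that reproduce published numbers (per-locus variability, multiplex
band sizes on deposited ITS records, genus monophyly under bootstrap) need
the deposited GenBank records as user-supplied FASTA under
`data/accessions/`; the library never fetches. Two caveats are inherent:
the published per-locus variation figures for indel-rich loci depend on
the original alignment (only the gap-free equal-length rbcL case is
alignment-independent), and the published band sizes require the deposited
ITS records to extend through the reverse-control annealing site — if they
are trimmed short, the check reports a truncation diagnostic instead of a
band table.

## Known limitations

* Tm is Wallace-rule only; no salt/enzyme corrections.
* No thermodynamic secondary-structure or degenerate-primer support.
* Circular templates and qPCR chemistry are out of scope.
* The progressive aligner is not a CLUSTAL/MAFFT replacement beyond
  desk-scale panels.
* Near-diagnostic (frequency-threshold) characters are supported via
  `min_target_freq` but population-genetic allele-frequency modelling is
  not attempted.
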