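"""Design an allele-specific multiplex panel on the packaged demo.

Loads the committed demo alignment (three assay targets plus one related
non-target species), designs one forward primer per target anchored with
its 3' terminus on a diagnostic motif plus a universal control pair, and
vets the panel for band separation and 3' cross-dimers.
"""

from barcodiag import design_panel, panel_check
from barcodiag.simulate import DEMO_TARGETS, krai_krue_demo

_, alignment, _, _ = krai_krue_demo()

panel = design_panel(alignment, targets=DEMO_TARGETS)
print("designed primers:")
for p in panel.primers:
    target = p.target_species or "all species"
    print(f"  {p.name:28s} {p.sequence:26s} Tm={p.tm_wallace:.0f}C  -> {target}")

print("expected bands (bp):", {sp: b[0] for sp, b in panel.expected_bands.items()})
print("internal control band:", panel.control_band, "bp")

report = panel_check(panel)
print("panel passes vetting:", report.passes)
print("Tm spread across the panel:", report.tm_spread, "C")

# Each species primer ends exactly on its species' private allele, so on any
# other species the 3' terminus mismatches and extension fails (the ARMS
# principle).  Band sizes are pairwise separated enough to resolve on an
# agarose gel, and every species product nests inside the control amplicon.
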