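"""Run the multiplex assay in silico and read band patterns as species calls.

Amplifies every demo individual with the packaged primer panel, renders a
virtual agarose gel, and classifies each lane: a control band plus exactly
one species band identifies a species; control only means a non-target
plant; no control at all means the reaction failed; control plus several
species bands flags a mixture.
"""

from barcodiag import call_species, multiplex_pcr, pool_lanes, render_gel_ascii
from barcodiag.simulate import krai_krue_demo

panel, _, truth, primer_panel = krai_krue_demo()

results = multiplex_pcr(primer_panel, panel)
lanes = []
for rec in panel.records[::3]:  # one individual per species
    amps, lane = results[rec.id]
    call = call_species(lane, primer_panel)
    print(f"{rec.id:24s} bands={list(lane.bands)!s:18s} call={call.call}")
    lanes.append(lane)

# pooled template: two species' genomic DNA in one tube
mix = pool_lanes("mixed_sample", [results[panel.records[0].id][1],
                                  results[panel.records[3].id][1]])
print(f"{'mixed_sample':24s} bands={list(mix.bands)!s:18s} "
      f"call={call_species(mix, primer_panel).call}")
lanes.append(mix)

print()
print(render_gel_ascii(lanes, height=16))
# Lanes read top to bottom from large to small fragments, like a real gel
# photographed with the wells at the top.
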