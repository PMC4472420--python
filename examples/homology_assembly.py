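"""Homology assembly: gap repair and a two-cycle overlap graph.

First a gap-repair cloning: a donor plasmid is opened with SalI (dropping
the marker between the two sites) and a tailed PCR product recombines into
the gap via 28/31 bp terminal homologies.

Then the graph semantics: five fragments whose shared homologies form two
circular subgraphs around one hub node.  All three circles -- each
subgraph's turn and their combination -- are reported, the largest first.
"""

from clonesim import assemble, cut, get_enzyme, pcr
from clonesim.synthetic import figure_eight_set, homology_cloning_scenario

hc = homology_cloning_scenario(seed=1)
backbone = max(cut(hc.donor, get_enzyme("SalI")), key=lambda f: f.span)
print("donor plasmid  :", hc.donor.short_repr())
print("SalI backbone  :", backbone.short_repr())
amplicon = pcr(hc.fwd, hc.rev, hc.template).product
print("tailed amplicon:", amplicon.short_repr())
res = assemble([amplicon, backbone], limit=25)
gap_repair = res.circular_products[0]
print("gap-repair circle:", gap_repair.molecule.short_repr())
print(gap_repair.figure())

print("\n--- two circular subgraphs sharing a hub ---")
frags = figure_eight_set(seed=1)
res2 = assemble(frags, limit=25)
print(res2.report())
for contig in res2.circular_products:
    print([entry[0] for entry in contig.path], "->",
          contig.molecule.short_repr())
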