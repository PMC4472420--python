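"""Classic cut-and-paste cloning, simulated end to end.

A gene is PCR-amplified with primers that add BamHI sites, the product is
digested and the middle fragment ligated into an expression vector opened
at its unique BglII site (BamHI and BglII leave the same GATC overhang).
Every intermediate length is printed; the final circle is the sum of the
linearized vector and the insert minus the 4 bp consumed at each of the
two sticky junctions.
"""

from clonesim import cut, get_enzyme, ligate, linearize, pcr
from clonesim.synthetic import sticky_ligation_scenario

scenario = sticky_ligation_scenario(seed=1)

print("vector           :", scenario.vector.short_repr())
backbone = linearize(scenario.vector, get_enzyme("BglII"))
print("BglII-linearized :", backbone.short_repr(),
      "(cohesive ends add 4 columns)")

amplicon = pcr(scenario.fwd, scenario.rev, scenario.template)
print("PCR product      :", amplicon.product.short_repr())

fragments = cut(amplicon.product, get_enzyme("BamHI"))
print("BamHI digest     :", [f.short_repr() for f in fragments])
middle = fragments[1]

products = [p for p in ligate([middle, backbone]) if p.circular]
construct = max(products, key=lambda p: p.span)
print("ligation circles :", [p.short_repr() for p in products])
print("final construct  :", construct.short_repr(),
      f"= {backbone.span} + {middle.span} - 2*4")
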