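"""PCR with tailed primers and inverse PCR on a circular template.

The 5' portion of a primer that does not anneal (the tail) is added to the
product; on a circular template the primers may face away from each other
across the origin.  The suggested thermocycler program is derived from the
footprint melting temperatures and the product length.
"""

from clonesim import AnnotatedMolecule, Primer, pcr, rc
from clonesim.synthetic import random_molecule

template = random_molecule(300, seed=11, id="demo_template")
f = template.fill()

fwd = Primer("fwd", "GGCCGGCC" + f[:18])          # 8 nt tail
rev = Primer("rev", "AATTAATT" + rc(f[-18:]))     # 8 nt tail
amp = pcr(fwd, rev, template)
print("linear template    :", template.short_repr())
print("tailed product     :", amp.product.short_repr(),
      "= 8 + 300 + 8 columns")
print(f"footprint Tm       : fwd {amp.tm_forward:.1f}C / rev {amp.tm_reverse:.1f}C")
print(amp.program)

circle = AnnotatedMolecule.from_string(f[:120], circular=True, id="plasmid")
g = circle.fill()
out_f = Primer("inv_f", (g + g)[110:110 + 16])    # crosses the origin
out_r = Primer("inv_r", rc((g + g)[60:60 + 16]))
inv = pcr(out_f, out_r, circle)
print("\ncircular template  :", circle.short_repr())
print("inverse PCR product:", inv.product.short_repr(),
      "(window runs through the origin)")
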