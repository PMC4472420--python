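"""Design tailed assembly primers, amplify, and close the circle.

Two genes are to be placed into a linearized vector by Gibson assembly or
in-vivo homologous recombination.  assembly_primers() balances each pair's
footprint melting temperatures and adds tails so adjacent PCR products --
and the vector ends -- share 35 bp of homology.  Running the designed PCRs
and assembling the products must yield the intended circle.
"""

from clonesim import assemble, assembly_primers, pcr
from clonesim.synthetic import random_molecule

gene1 = random_molecule(620, seed=21, id="gene1")
gene2 = random_molecule(480, seed=22, id="gene2")
vector = random_molecule(1400, seed=23, id="vector")

pairs = assembly_primers([gene1, gene2], vector=vector,
                         target_tm=60, overlap=35)
for (fwd, rev), frag in zip(pairs, (gene1, gene2)):
    print(f"{frag.id}: fwd {len(fwd.sequence)} nt, rev {len(rev.sequence)} nt")

products = [pcr(fwd, rev, frag).product
            for (fwd, rev), frag in zip(pairs, (gene1, gene2))]
print("PCR products:", [p.short_repr() for p in products])

result = assemble(products + [vector], limit=25)
print(result.report())
circle = result.circular_products[0]
print(circle.figure())
print("every junction >= 35 bp:", all(ol >= 35 for _, _, ol in circle.path))
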