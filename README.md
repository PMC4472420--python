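# clonesim

Deterministic, scriptable simulation of DNA cloning. A cloning strategy
written as a short Python program — restriction digestion, ligation, PCR
with tailed primers, automatic assembly-primer design, Gibson/homologous-
recombination assembly — yields the exact sequence of every intermediate
and final construct, so a strategy can be planned, verified and shared as
executable code instead of an ad-hoc lab-notebook narrative.

It is written for molecular biologists and synthetic-biology engineers who
plan multi-fragment constructs: the unit operations read like the methods
section of a cloning paper, and every operation returns ordinary molecule
objects that can be inspected, sliced and fed into the next step.

## The model

**Duplex molecules.** A molecule is two antiparallel strands plus an
integer *stagger* describing how they align, which is exactly the state
needed for cohesive ("sticky") ends: BamHI's `G^GATCC` leaves a 5'-GATC
overhang, BglII's `A^GATCT` the same, so their fragments ligate. The
*span* of a molecule counts alignment columns covered by either strand —
opening a 9637 bp circle at a BglII site therefore yields a 9641 bp
linear molecule, the length a gel shows. Circular topology, feature
tables and GenBank/FASTA round trips are first-class.

**PCR.** A primer anneals where its 3'-terminal ≥ 13 nt match the
template exactly; the 5' remainder (tail) is added to the product.
Inverse PCR across the origin of circular templates is supported, and
template features fully contained in the amplified window carry over.
Footprint melting temperatures use nearest-neighbor thermodynamics
(Allawi & SantaLucia 1997, 50 mM Na⁺, 500/25 nM strands).

**Primer design.** `assembly_primers(fragments, vector=...)` picks
Tm-balanced footprints (target 60 °C, pair balanced within 2 °C) and adds
tails so adjacent PCR products — and the vector ends — share ≥ 35 bp,
ready for Gibson assembly or in-vivo recombination.

**Assembly.** Three steps: (1) all fragment pairs (both relative
orientations) are scanned for shared subsequences ≥ 25 bp using a suffix
array built with the linear-time skew (DC3) algorithm plus Kasai's LCP
array; overlaps are annotated as features. (2) A directed multigraph is
built whose nodes are the overlap sequences, bracketed by 5' and 3'
terminal nodes, with intervening fragment stretches as edges. (3) Linear
products are all simple 5'→3' paths; circular products are simple cycles
plus one-turn compositions of node-sharing cycles, so when two circular
subgraphs share a node the largest combined product is always reported.
Products are deduplicated by a rotation- and strand-invariant canonical
form.

## Worked example

`examples/restriction_cloning.py` simulates a classic insert-into-vector
strategy on a seeded synthetic vector/gene pair (the package bundles no
sequence data; the `clonesim.synthetic` module generates study inputs
deterministically):

```
vector           : o9637
BglII-linearized : -9641 (cohesive ends add 4 columns)
PCR product      : -1825
BamHI digest     : ['-7', '-1819', '-7']
ligation circles : ['o11452', 'o11452', 'o9637', 'o1815']
final construct  : o11452 = 9641 + 1819 - 2*4
```

Reading the output: `o`/`-` tag circular/linear topology, the number is
the span in bp. The tailed 1825 bp amplicon loses two 7 bp stuffers to
BamHI; ligating the 1819 bp insert into the 9641 bp linearized vector
consumes 4 bp at each sticky junction, giving the 11452 bp construct (the
two `o11452` entries are the two insert orientations; `o9637` is the
re-ligated empty vector and `o1815` the self-circularized insert).

The other examples cover tailed/inverse PCR (`pcr_simulation.py`),
the design→PCR→assembly closed loop (`primer_design.py`) and gap-repair
plus two-subgraph assembly semantics (`homology_assembly.py`), e.g.:

```
circular products....: 3 [o791 o479 o312]
['fragD', 'fragE', 'fragA', 'fragB', 'fragC'] -> o791
```

— five fragments forming two homology circles around a shared hub yield
both subcircles and their combination, the largest product.

## Command line

`clonesim digest|pcr|design|assemble|fetch|demo-data` expose the unit
operations for shell pipelines; each is a thin wrapper producing output
byte-identical to the library calls. Exit codes: 0 success, 2 user error,
3 no result.
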