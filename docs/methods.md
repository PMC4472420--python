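# Methods

## The duplex model

A DNA molecule is represented by its two strands (each stored 5'→3') and
an integer stagger giving their alignment offset at the left end; the
topology flag marks closed circles, which by definition carry no
overhangs. All coordinates are 0-based and half-open on the watson
strand; origin-spanning features on circles are stored with start > end
and interpreted modulo the span. Display layers may add 1 where
biologists expect 1-based positions.

The *span* of a molecule is the number of alignment columns covered by
either strand. This convention is forced by the arithmetic of sticky
ends: a circle of n bp opened by a 4-nt 5'-overhang cutter must read
n + 4 — each strand still has n nucleotides, but the duplex covers four
extra columns. All lengths printed by the package (`short_repr`, reports,
contig figures) are spans.

Ends are reported as `(kind, sequence)` with kind ∈ {blunt, 5', 3'} and
the protruding single strand read 5'→3'. Two ends ligate iff both are
blunt, or the kinds match and one overhang is the reverse complement of
the other — the idealized T4 ligase rule, with no partial or mismatched
annealing. Windowing operations (slicing, PCR carry-over, digestion
inheritance) keep a feature only when it lies fully inside the window;
one rule everywhere keeps coordinates predictable.

Molecules are compared by a canonical form: for circles the
lexicographically least rotation over the filled sequence and its reverse
complement (Booth's least-rotation algorithm), for linear molecules the
smaller of the filled sequence and its reverse complement. Slicing and
GenBank export fill single-stranded overhang columns with their
complement (a polymerase fill-in); GenBank cannot represent sticky ends,
so exported sticky molecules are blunted and a comment records that.

## Restriction and ligation

Enzymes are (name, IUPAC site, watson-cut offset, crick-cut offset); the
offset difference gives overhang length and sign. A small static table
(BamHI, BglII, SalI, EcoRI, HindIII, XbaI, XhoI, NotI, PstI, SacI, KpnI,
ZraI, AjiI, EcoRV, SmaI) ships as a plain TSV so digestion needs no
external database; `register_enzyme` is the extension point. Sites are
found on both strands, IUPAC-aware, across the origin of circles;
fragments come back in positional order along the parent.

`ligate()` enumerates every product of joining the given fragments — each
used at most once, either orientation, sticky or blunt ends — returning
both circular closures (including single-fragment self-circularization)
and linear chains of two or more fragments, deduplicated by canonical
form. The enumeration is exponential by nature and guarded at 8 fragments
by default; real cloning steps use two or three.

## PCR

A primer anneals wherever its 3'-terminal `min_footprint` (default 13)
nucleotides match a template strand exactly; the longest exact 3' match
is the footprint, the 5' remainder the tail. Thirteen was chosen as the
shortest footprint that is unlikely to occur by chance on plasmid-scale
templates (4¹³ ≈ 6.7 × 10⁷) while still tolerating short designed
footprints; it is configurable. Mismatched annealing is not modelled —
the simulation is deterministic by design.

The product is forward tail + template window + reverse complement of the
reverse tail. On circular templates the window runs forward from the
forward footprint's 5' base to the reverse footprint's 5' base, wrapping
the origin as needed; when the two annealing regions overlap around a
small circle the window wraps far enough to contain both footprints
whole, so inverse PCR with back-to-back primers behaves correctly. A
simulation requires exactly one productive primer pairing; zero raises
`NoAmpliconError` and several raise `AmbiguousProductError` carrying all
candidate products (or pass `all_products=True`).

Melting temperatures use Biopython's nearest-neighbor `Tm_NN` with the
Allawi & SantaLucia (1997) parameter set, 50 mM Na⁺, and 500 nM primer
over 25 nM template — a typical PCR primer excess; all are overridable
keyword arguments. Only the footprint enters the Tm. The suggested
thermocycler program is a labelled heuristic: annealing at the lower
footprint Tm − 3 °C, extension at 1 kb/min rounded up to whole minutes.

## Assembly-primer design

For each fragment the footprint grows from the terminus until its Tm
reaches the target (default 60 °C); the pair is then balanced by a small
grid search over footprint lengths (window doubling from 8 until the
tolerance, default 2 °C, is met), preferring the smallest Tm difference
and then the shortest primers. Overlap tails are split between adjacent
products — ⌈overlap/2⌉ nucleotides copied from the upstream fragment's
end onto the downstream forward primer, ⌊overlap/2⌋ from the downstream
start onto the upstream reverse primer — which keeps primer lengths
balanced; the guarantee is shared terminal identity ≥ the overlap
parameter (default 35 bp, inside the 30–50 bp range effective for yeast
recombination and Gibson assembly). A vector is never amplified: the
first forward and last reverse primers instead carry a full `overlap` of
homology to the vector's right and left ends. Fragments are used exactly
in the order and orientation given.

## Homology assembly

Step 1 — homology search. Every fragment pair is compared in both
relative orientations for maximal shared substrings of length ≥ `limit`
(default 25 bp, the conventional lower bound for reliable in-vivo
junctions). The search builds the suffix array of `a + SEP + b` with a
pure-Python implementation of the linear-time skew (DC3) construction and
Kasai's LCP array, then scans LCP blocks for cross-string pairs,
reporting only left-maximal matches (same-diagonal containments are
suppressed). Detected regions become `overlap` features on each fragment,
minus-strand when the region matches the partner's reverse complement.

Step 2 — graph. Nodes are distinct overlap nucleotide strings plus 5'/3'
terminals; each fragment enters in both orientations, contributing edges
from 5' through its overlap occurrences (every non-overlapping ordered
pair of occurrences) to 3', each edge carrying the fragment index,
orientation and intervening sequence. Keying nodes by sequence means two
distinct loci with identical ≥ limit sequence collapse to one node; that
is inherent to the sequence-only model and can merge distinct designs
that reuse a sequence block.

Step 3 — products. Linear products are all simple 5'→3' paths whose
edges use each fragment at most once; this includes single-fragment
paths (a fragment that shares homology is itself a trivial product) and
degenerate junction-only products where a path keeps nothing but the
shared region — both are consistent outcomes of the all-paths convention
and are documented rather than filtered. Circular products are simple
cycles of the overlap-node subgraph plus compositions of node-sharing,
fragment-disjoint cycles, each cycle turned at most once, spliced at the
first shared-node occurrence; with two subgraphs sharing a hub this
reports both subcircles and their combination, the largest product.
Enumeration is bounded (500 paths, 50 circular candidates by default) to
guard pathological graphs. Products are deduplicated by canonical form
and sorted by descending span, then lexicographically — all output is
deterministic.

Self-homology within a single fragment (a fragment whose own ends repeat)
is not searched; only pairwise homologies create nodes. Junction
chemistry is not modelled: Gibson assembly and in-vivo single-strand
annealing give the same sequence outcome here, and no statement is made
about recombination efficiency or which product a real experiment favors.

## Synthetic study inputs

The package bundles no sequence data; `clonesim.synthetic` generates
every input deterministically from a seed. `overlapping_fragments`
produces chains (optionally closed) joined by designed terminal overlaps;
`figure_eight_set` produces five fragments whose overlap graph holds
exactly two cycles sharing one hub node. All filler sequence is
rejection-sampled until no unintended shared substring at the assembly
limit remains, so generated topologies are exact rather than probable.

Two scenario builders are synthetic stand-ins for classic published
constructions. `sticky_ligation_scenario` emulates cloning a kinase gene
into a yeast expression vector: a 9637 bp circular vector with a unique
BglII site and no BamHI site, plus a gene template and BamHI-tailed
primers sized so the digested insert spans 1819 columns — linearization
gives 9641 bp and ligation an 11452 bp circle. `homology_cloning_scenario`
emulates a gap-repair cloning: a 9465 bp donor with two SalI sites 1648 bp
apart (7821 bp backbone) and primers with 28/31 nt backbone-homology
tails around a 2160 nt window, closing a 9981 bp circle. The sizes and
cut-site geometry match the original constructions; every base pair is
random per seed. What passing these scenarios shows is that the engine's
bookkeeping (overhang columns, junction consumption, homology stitching)
is exact; it says nothing about sequence-specific effects in real
molecules — repeats, secondary structure, or star activity — which the
model deliberately excludes.

Acceptance runs use these generator defaults unchanged: limit 25 bp,
overlap 35 bp, target Tm 60 °C, tolerance 2 °C, min footprint 13 nt.
The test suite cross-checks each algorithmic core against an independent
oracle: suffix arrays against naive suffix sorting, common substrings
against an O(n·m) dynamic program, site finding against rotate-and-scan
and Bio.Restriction, ligation and assembly against brute-force
order/orientation enumerators (n ≤ 4–5 fragments, spans ≤ 300, limit
15–25 — sizes chosen to keep the factorial oracles exhaustive yet fast),
and Tm against a from-scratch nearest-neighbor implementation.

## Known limitations

* Exact-match joins only: no mismatch-tolerant overlaps, no partial
  sticky-end annealing, no methylation or star activity.
* Node identity by overlap sequence collapses identical loci (above).
* Cycle composition splices at the first shared-node occurrence; deeply
  nested cactus graphs may not enumerate every interleaving beyond the
  largest combined product.
* `ligate()` and path enumeration are combinatorial; the guards exist
  because blunt fragment sets explode factorially.
* GenBank export blunts sticky ends (format limitation, noted in the
  record); the cache is keyed by accession string with no version
  resolution.
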