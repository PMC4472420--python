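"""Seeded synthetic molecules for offline simulation and testing.

Everything here is generated programmatically and deterministically from a
seed: random molecules, fragment sets with designed terminal overlaps, a
five-fragment set whose overlap graph holds two node-sharing cycles, and
two complete surrogate cloning scenarios (a sticky-end restriction/ligation
strategy and a tailed-primer homology strategy).

The two scenario builders are *synthetic stand-ins* for classic published
constructions (a yeast expression vector receiving a xylulokinase gene via
BamHI/BglII ligation, and a GUP1 expression plasmid built by gap-repair
homologous recombination).  The real GenBank records are not bundled;
instead the generators produce random-sequence plasmids engineered to the
same sizes and cut-site geometry, so the construction arithmetic of the
originals (9637 bp circle -> 9641 bp linear; 11452 bp and 9981 bp final
circles) is reproduced exactly while every base pair is synthetic.

Inter-overlap filler sequence is rejection-sampled so that fragment sets
contain no unintended repeats at the assembly limit; generated topologies
are therefore exact, not merely probable.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass

from .amplify import Primer
from .assembly import common_substrings
from .duplex import reverse_complement
from .record import AnnotatedMolecule

_MAX_ATTEMPTS = 60


def _rdna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _scrub(rng: random.Random, seq: str, patterns, circular: bool = False) -> str:
    """Mutate single bases until none of ``patterns`` occurs (wrap-aware)."""
    seq = list(seq)
    maxlen = max(map(len, patterns)) if patterns else 1
    while True:
        s = "".join(seq)
        text = s + s[:maxlen - 1] if circular else s
        hit = None
        for pat in patterns:
            m = re.search("(?=" + pat + ")", text)
            if m:
                hit = (m.start(), len(pat))
                break
        if hit is None:
            return s
        pos = (hit[0] + hit[1] // 2) % len(seq)
        seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])


def random_molecule(length: int, circular: bool = False, seed: int = 0,
                    id: str = "synmol") -> AnnotatedMolecule:
    """Uniform random molecule, reproducible from the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = random.Random(seed)
    return AnnotatedMolecule.from_string(_rdna(rng, length), circular, id=id)


def _spurious_overlap(fragments, designed, limit) -> bool:
    """Any shared substring >= limit beyond the designed set?"""
    fills = [f.fill() for f in fragments]
    for i in range(len(fills)):
        for j in range(i + 1, len(fills)):
            for orient, b in ((1, fills[j]), (-1, reverse_complement(fills[j]))):
                got = {(i, j, orient, m.start_a, m.start_b, m.length)
                       for m in common_substrings(fills[i], b, limit)}
                if got != designed.get((i, j, orient), set()):
                    return True
    return False


def overlapping_fragments(n: int, span_range=(200, 1000), overlap_len: int = 30,
                          circular_closure: bool = False, seed: int = 0,
                          limit: int = 25):
    """``n`` fragments chained by designed terminal overlaps.

    Fragment i's terminal ``overlap_len`` nucleotides equal fragment i+1's
    initial ones; with ``circular_closure`` the last fragment also feeds
    back into the first.  All other content is rejection-sampled to share
    nothing of length >= ``limit``, so assembling the set yields exactly
    one maximal product (circular with closure, linear without).
    """
    if n < 2:
        raise ValueError("need at least two fragments")
    if overlap_len >= min(span_range):
        raise ValueError("overlap_len must be smaller than the smallest span")
    rng = random.Random(seed)
    for _ in range(_MAX_ATTEMPTS):
        spans = [rng.randint(*span_range) for _ in range(n)]
        joins = [_rdna(rng, overlap_len) for _ in range(n if circular_closure
                                                        else n - 1)]
        frags = []
        designed = {}
        for i in range(n):
            left = joins[i - 1] if (i > 0 or circular_closure) else ""
            right = joins[i] if i < len(joins) else ""
            filler = max(spans[i] - len(left) - len(right), 10)
            seq = left + _rdna(rng, filler) + right
            frags.append(AnnotatedMolecule.from_string(seq, id=f"frag{i + 1}"))
        for i in range(n):
            nxt = i + 1
            if nxt < n or circular_closure:
                j = nxt % n
                a, b = (i, j) if i < j else (j, i)
                fa, fb = frags[a].fill(), frags[b].fill()
                if i < j:
                    sa, sb = len(fa) - overlap_len, 0
                else:  # closure join seen from the smaller index
                    sa, sb = 0, len(fb) - overlap_len
                designed.setdefault((a, b, 1), set()).add(
                    (a, b, 1, sa, sb, overlap_len))
        if not _spurious_overlap(frags, designed, min(limit, overlap_len)):
            return frags
    raise RuntimeError("could not sample an overlap-clean fragment set")


def figure_eight_set(seed: int = 0, overlap_len: int = 30, limit: int = 25):
    """Five fragments whose overlap graph holds two cycles sharing a node.

    Fragments A,B,C close one circular subgraph (via overlaps u, v and the
    hub h) and D,E a second one (via w and the same hub h).  Assembling
    the set yields exactly three circular products: each subcircle and
    their combination, the largest product.
    """
    rng = random.Random(seed)
    for _ in range(_MAX_ATTEMPTS):
        h, u, v, w = (_rdna(rng, overlap_len) for _ in range(4))
        mk = AnnotatedMolecule.from_string
        frags = [
            mk(h + _rdna(rng, rng.randint(100, 160)) + u, id="fragA"),
            mk(u + _rdna(rng, rng.randint(100, 160)) + v, id="fragB"),
            mk(v + _rdna(rng, rng.randint(100, 160)) + h, id="fragC"),
            mk(h + _rdna(rng, rng.randint(100, 160)) + w, id="fragD"),
            mk(w + _rdna(rng, rng.randint(100, 160)) + h, id="fragE"),
        ]
        designed = {}

        def add(i, j, sa, sb, ln=overlap_len):
            designed.setdefault((i, j, 1), set()).add((i, j, 1, sa, sb, ln))

        spans = [f.span for f in frags]
        add(0, 1, spans[0] - overlap_len, 0)          # u
        add(1, 2, spans[1] - overlap_len, 0)          # v
        add(0, 2, 0, spans[2] - overlap_len)          # h: A start, C end
        add(0, 3, 0, 0)                               # h: A start, D start
        add(2, 3, spans[2] - overlap_len, 0)          # h: C end, D start
        add(2, 4, spans[2] - overlap_len, spans[4] - overlap_len)  # h
        add(0, 4, 0, spans[4] - overlap_len)          # h: A start, E end
        add(3, 4, spans[3] - overlap_len, 0)          # w
        add(3, 4, 0, spans[4] - overlap_len)          # h: D start, E end
        if not _spurious_overlap(frags, designed, min(limit, overlap_len)):
            return frags
    raise RuntimeError("could not sample a clean two-cycle fragment set")


# ---------------------------------------------------------------------------
# Surrogate end-to-end cloning scenarios
# ---------------------------------------------------------------------------

@dataclass
class StickyLigationScenario:
    """Synthetic restriction/ligation strategy (BamHI insert into BglII site).

    ``vector`` is a circular 9637 bp plasmid with a unique BglII site and
    no BamHI site; ``template`` carries the gene of interest; the primers
    add BamHI tails.  PCR, BamHI digestion (keep the middle fragment),
    BglII linearization of the vector and ligation yield an 11452 bp
    circular construct -- the arithmetic of the classic yeast
    xylulokinase cloning this scenario stands in for.
    """

    vector: AnnotatedMolecule
    template: AnnotatedMolecule
    fwd: Primer
    rev: Primer


def _site_positions(seq: str, site: str, circular: bool):
    text = seq + seq[:len(site) - 1] if circular else seq
    return sorted({m.start() % len(seq)
                   for m in re.finditer("(?=" + site + ")", text)})


def sticky_ligation_scenario(seed: int = 0) -> StickyLigationScenario:
    rng = random.Random(seed)
    bam, bgl = "GGATCC", "AGATCT"
    # the amplified window must leave a 1819-column middle fragment after
    # BamHI digestion (8 nt GC+GGATCC tails, watson cuts at offset 3)
    window, pad, footprint = 1809, 60, 22
    for _ in range(_MAX_ATTEMPTS):
        # circular expression vector: 9637 bp, unique BglII, BamHI-free
        core = _scrub(rng, _rdna(rng, 9631), [bam, bgl])
        vec_seq = _scrub(rng, bgl + core, [bam], circular=True)
        if (_site_positions(vec_seq, bgl, True) != [0]
                or _site_positions(vec_seq, bam, True)):
            continue
        tpl_seq = _scrub(rng, _rdna(rng, window + 2 * pad), [bam, bgl])
        fwd_seq = "GC" + bam + tpl_seq[pad:pad + footprint]
        rev_seq = "GC" + bam + reverse_complement(
            tpl_seq[pad + window - footprint:pad + window])
        # unique annealing: each 13-nt 3' seed occurs once over both strands
        text = tpl_seq + "#" + reverse_complement(tpl_seq)
        if not (text.count(fwd_seq[-13:]) == 1 and text.count(rev_seq[-13:]) == 1):
            continue
        # the PCR product must carry exactly the two tail BamHI sites
        product_seq = fwd_seq + tpl_seq[pad + footprint:pad + window - footprint] \
            + reverse_complement(rev_seq)
        if len(_site_positions(product_seq, bam, False)) != 2:
            continue
        vector = AnnotatedMolecule.from_string(
            vec_seq, circular=True, id="synthetic_vector",
            description="synthetic 9637 bp expression vector (unique BglII)")
        template = AnnotatedMolecule.from_string(
            tpl_seq, id="synthetic_gene_template",
            description="synthetic kinase gene template")
        return StickyLigationScenario(vector, template,
                                      Primer("primer1", fwd_seq),
                                      Primer("primer3", rev_seq))
    raise RuntimeError("could not sample a clean sticky-ligation scenario")


@dataclass
class HomologyCloningScenario:
    """Synthetic gap-repair strategy (SalI-opened vector + tailed PCR insert).

    ``donor`` is a circular 9465 bp plasmid with exactly two SalI sites
    flanking a marker; double digestion yields a 7821 bp backbone.  The
    primers amplify the gene from ``template`` with 28 and 31 nt tails
    homologous to the backbone ends, and two-fragment homology assembly
    closes a 9981 bp circle -- the arithmetic of the classic GUP1
    gap-repair cloning this scenario stands in for.
    """

    donor: AnnotatedMolecule
    template: AnnotatedMolecule
    fwd: Primer
    rev: Primer


def homology_cloning_scenario(seed: int = 0) -> HomologyCloningScenario:
    rng = random.Random(seed)
    sal = "GTCGAC"
    p1, p2 = 100, 1748            # sites 1648 apart: marker 1652, rest 7821
    window, pad, footprint = 2160, 50, 21
    tail_right, tail_left = 28, 31  # homology to backbone right/left ends
    for _ in range(_MAX_ATTEMPTS):
        body = _scrub(rng, _rdna(rng, 9465), [sal], circular=True)
        donor_seq = (body[:p1] + sal + body[p1 + 6:p2] + sal + body[p2 + 6:])
        donor_seq = donor_seq[:9465]
        sites = [m.start() % 9465 for m in
                 re.finditer("(?=" + sal + ")", donor_seq + donor_seq[:5])]
        if sorted(set(sites)) != [p1, p2]:
            continue
        donor = AnnotatedMolecule.from_string(
            donor_seq, circular=True, id="synthetic_donor",
            description="synthetic 9465 bp donor plasmid (two SalI sites)")
        # the backbone is the larger SalI fragment
        from .restriction import cut, get_enzyme
        frags = cut(donor, get_enzyme("SalI"))
        backbone = max(frags, key=lambda f: f.span)
        if backbone.span != 7821:
            continue
        fb = backbone.fill()
        tpl_seq = _scrub(rng, _rdna(rng, window + 2 * pad), [sal])
        fwd_seq = fb[-tail_right:] + tpl_seq[pad:pad + footprint]
        rev_seq = reverse_complement(fb[:tail_left]) + reverse_complement(
            tpl_seq[pad + window - footprint:pad + window])
        text = tpl_seq + "#" + reverse_complement(tpl_seq)
        if not (text.count(fwd_seq[-13:]) == 1 and text.count(rev_seq[-13:]) == 1):
            continue
        # designed homology only: product ends vs backbone ends
        product_like = fwd_seq + tpl_seq[pad + footprint:pad + window - footprint] \
            + reverse_complement(rev_seq[:tail_left])
        probe = [AnnotatedMolecule.from_string(product_like, id="p"), backbone]
        designed = {(0, 1, 1): {
            (0, 1, 1, 0, len(fb) - tail_right, tail_right),
            (0, 1, 1, len(product_like) - tail_left, 0, tail_left)}}
        if _spurious_overlap(probe, designed, 25):
            continue
        template = AnnotatedMolecule.from_string(
            tpl_seq, id="synthetic_orf_template",
            description="synthetic membrane-protein ORF template")
        return HomologyCloningScenario(donor, template,
                                       Primer("rec1_sense", fwd_seq),
                                       Primer("rec2_anti", rev_seq))
    raise RuntimeError("could not sample a clean homology-cloning scenario")
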