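"""PCR simulation: primer annealing, amplification and melting temperature.

The simulation is deterministic and exact-match only: a primer anneals
where its 3'-terminal ``min_footprint`` (default 13) or more nucleotides
match the template perfectly; the longest such 3' match is the footprint
and any 5' remainder is a tail that is added to the product.  Inverse PCR
on circular templates (primer pairs straddling the origin) is supported.
Template features fully contained in the amplified window are carried
over into the product; features crossing the window boundary are dropped.

Melting temperatures are computed for primer footprints only (the part
that actually anneals) with nearest-neighbor thermodynamics via
Biopython's ``Tm_NN`` -- Allawi & SantaLucia (1997) parameters, 50 mM
Na+, 500 nM primer over 25 nM template (pinned for reproducibility,
configurable through keyword arguments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from .duplex import DuplexSequence, reverse_complement
from .errors import AmbiguousProductError, NoAmpliconError
from .record import AnnotatedMolecule, features_in_window

WATSON = "watson"
CRICK = "crick"

DEFAULT_MIN_FOOTPRINT = 13


@dataclass(frozen=True)
class Primer:
    """A single-stranded oligonucleotide, 5'->3'."""

    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq or seq.strip("ACGT"):
            raise ValueError(f"primer {self.id!r} must be non-empty A/C/G/T")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerAnnealing:
    """One exact annealing of a primer's 3' end on a template strand.

    ``footprint_start`` is the template (watson-strand) coordinate of the
    primer's 3'-most annealed base.  ``primer.sequence == tail + footprint``.
    """

    primer: Primer
    template_strand: str   # WATSON or CRICK
    footprint_start: int
    footprint_length: int
    tail: str

    @property
    def footprint(self) -> str:
        return self.primer.sequence[len(self.tail):]


def melting_temperature(seq: str, **kw) -> float:
    """Nearest-neighbor melting temperature of a primer footprint, in C.

    Deterministic wrapper around ``Bio.SeqUtils.MeltingTemp.Tm_NN``:
    Allawi & SantaLucia (1997) parameters, 50 mM Na+, and a typical PCR
    situation of 500 nM primer in large excess over template (25 nM).
    Keyword arguments override the pinned defaults and are passed straight
    through to Biopython.
    """
    if not seq:
        raise ValueError("cannot compute a melting temperature of nothing")
    kw.setdefault("dnac1", 500)
    kw.setdefault("dnac2", 25)
    return float(_mt.Tm_NN(seq, **kw))


def anneal(primers, template: AnnotatedMolecule,
           min_footprint: int = DEFAULT_MIN_FOOTPRINT):
    """Every position where a primer's 3' end matches the template exactly.

    Both strands are searched; circular templates are searched across the
    origin.  For each position the longest exact 3'-terminal match of the
    primer is the footprint and the 5' remainder the tail.  Returns a list
    of :class:`PrimerAnnealing`, empty when nothing anneals.
    """
    primers = list(primers)
    span = template.span
    if span == 0 or not primers:
        return []
    f = template.fill()
    ext = min(span, max(len(p.sequence) for p in primers)) - 1
    best = {}  # (primer idx, strand, 3'-end col) -> footprint length
    for strand_name, strand_seq in ((WATSON, f), (CRICK, reverse_complement(f))):
        text = strand_seq + strand_seq[:ext] if template.circular else strand_seq
        for pi, primer in enumerate(primers):
            seq = primer.sequence
            if len(seq) < min_footprint:
                continue
            seed = seq[-min_footprint:]
            pos = text.find(seed)
            while pos != -1:
                e = pos + min_footprint - 1  # 3'-most base, text index
                k = min_footprint
                while (k < len(seq) and k < span and e - k >= 0
                       and seq[-(k + 1)] == text[e - k]):
                    k += 1
                if strand_name == WATSON:
                    col = e % span
                else:
                    col = (span - 1 - (e % span)) % span
                key = (pi, strand_name, col)
                if k > best.get(key, 0):
                    best[key] = k
                pos = text.find(seed, pos + 1)
    results = []
    for (pi, strand_name, col), k in best.items():
        primer = primers[pi]
        results.append(PrimerAnnealing(primer, strand_name, col, k,
                                       primer.sequence[:len(primer.sequence) - k]))
    results.sort(key=lambda a: (a.template_strand, a.footprint_start, a.primer.id))
    return results


@dataclass
class AmplificationProduct:
    """A simulated amplicon with its annealing geometry and program."""

    product: AnnotatedMolecule
    forward: PrimerAnnealing
    reverse: PrimerAnnealing
    tm_forward: float
    tm_reverse: float
    program: str

    @property
    def span(self) -> int:
        return self.product.span

    def __repr__(self) -> str:
        return f"AmplificationProduct({self.product.short_repr()})"


def _suggested_program(tm_fwd: float, tm_rev: float, span: int) -> str:
    """Deterministic, heuristic thermocycler schedule.

    Annealing 3 C below the lower footprint Tm; extension at 1 kb/min
    rounded up to whole minutes.
    """
    ta = min(tm_fwd, tm_rev) - 3.0
    ext_min = max(1, math.ceil(span / 1000))
    return "\n".join([
        "denaturation 95C 2:00",
        f"30 cycles of [95C 0:30 | {ta:.1f}C 0:30 | 72C {ext_min}:00]",
        "final extension 72C 5:00",
        f"product {span} bp; annealing {ta:.1f}C (lower footprint Tm - 3C); "
        f"extension {ext_min} min (1 kb/min, rounded up)",
    ])


def pcr(forward: Primer, reverse: Primer, template: AnnotatedMolecule,
        min_footprint: int = DEFAULT_MIN_FOOTPRINT, all_products: bool = False):
    """Simulate PCR of ``template`` with one primer pair.

    The two primers must anneal on opposite strands with their 3' ends
    facing each other; on a circular template any such pair is productive
    across the origin (inverse PCR).  Exactly one productive pair must
    exist, otherwise :class:`NoAmpliconError` or
    :class:`AmbiguousProductError` is raised (pass ``all_products=True``
    to get the full list instead of the ambiguity error).

    The product is a blunt linear molecule::

        forward tail + template window + reverse-complement(reverse tail)

    carrying every template feature fully contained in the window.
    """
    span = template.span
    f = template.fill()
    anns = anneal([forward, reverse], template, min_footprint)
    watson_anns = [a for a in anns if a.template_strand == WATSON]
    crick_anns = [a for a in anns if a.template_strand == CRICK]

    candidates = []
    for wa in watson_anns:
        for ca in crick_anns:
            # a valid pair uses one primer on each strand (identical
            # primer objects may legitimately serve both roles)
            if wa.primer is ca.primer and forward is not reverse:
                continue
            # watson-side 5' column and footprint extent
            a0 = wa.footprint_start - wa.footprint_length + 1
            # crick annealing occupies watson cols [ca.footprint_start,
            # ca.footprint_start + L); its 5'-most base is the highest col
            y5 = ca.footprint_start + ca.footprint_length - 1
            if template.circular:
                a0m = a0 % span
                wl = (y5 - a0m) % span + 1
                # the window must contain both footprints whole; wrap
                # further if the annealing regions straddle the origin
                while wl < max(wa.footprint_length, ca.footprint_length):
                    wl += span
                candidates.append((wa, ca, a0m, wl))
            else:
                if a0 < 0 or y5 >= span:
                    continue
                x3 = wa.footprint_start
                y3 = ca.footprint_start
                if x3 > y5 or y3 < a0:
                    continue  # 3' ends do not face each other
                candidates.append((wa, ca, a0, y5 - a0 + 1))

    products = []
    for wa, ca, a0, wl in candidates:
        if template.circular:
            window = (f * 3)[a0:a0 + wl]
        else:
            window = f[a0:a0 + wl]
        fwd_tail = wa.tail
        rev_tail = ca.tail
        seq = fwd_tail + window + reverse_complement(rev_tail)
        feats = features_in_window(template.features, a0, wl, span,
                                   template.circular)
        for feat in feats:
            feat.start += len(fwd_tail)
            feat.end += len(fwd_tail)
        product = AnnotatedMolecule(
            DuplexSequence.from_string(seq),
            id=f"{len(seq)}bp_amplicon",
            description=f"PCR product {wa.primer.id}/{ca.primer.id}",
            features=feats)
        tm_f = melting_temperature(wa.footprint)
        tm_r = melting_temperature(ca.footprint)
        prog = _suggested_program(tm_f, tm_r, product.span)
        products.append(AmplificationProduct(product, wa, ca, tm_f, tm_r, prog))

    products.sort(key=lambda p: (-p.span, p.product.canonical_form()))
    if not products:
        raise NoAmpliconError(
            f"no productive {forward.id}/{reverse.id} pair on {template.id}")
    if len(products) > 1:
        if all_products:
            return products
        raise AmbiguousProductError(
            f"{len(products)} products from {forward.id}/{reverse.id} on "
            f"{template.id}: " + ", ".join(str(p.span) for p in products),
            products)
    return products[0]
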