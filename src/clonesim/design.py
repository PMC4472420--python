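"""Automatic design of tailed primers for multi-fragment assembly.

Given an ordered series of linear fragments (and optionally a linearized
vector backbone), :func:`assembly_primers` designs one forward/reverse
primer pair per fragment such that

* each primer's annealing footprint reaches at least a target melting
  temperature (default 60 C) and the two footprints of a pair are
  balanced within a tolerance (default 2 C), and
* the PCR products of adjacent fragments share at least ``overlap``
  (default 35) identical terminal nucleotides, so the products can be
  joined by Gibson assembly or in-vivo homologous recombination.

The overlap between two adjacent products is split between them: the
upstream fragment's reverse primer receives a tail copying the first
ceil(overlap/2) nucleotides of the downstream fragment, and the
downstream fragment's forward primer a tail copying the last
floor(overlap/2) nucleotides of the upstream fragment.  When a vector is
given, no primers are designed for it; instead the first fragment's
forward tail carries ``overlap`` nucleotides of homology to the vector's
right end and the last fragment's reverse tail to the vector's left end.

Fragments are used exactly in the order and orientation given -- the
function never flips a fragment to make an assembly work.
"""

from __future__ import annotations

from .amplify import Primer, melting_temperature
from .duplex import reverse_complement
from .errors import DesignError
from .record import AnnotatedMolecule

DEFAULT_TARGET_TM = 60.0
DEFAULT_OVERLAP = 35
DEFAULT_TM_TOLERANCE = 2.0
MIN_FOOTPRINT = 13


def _footprint_reaching(seq: str, target_tm: float, what: str) -> int:
    """Shortest prefix length >= MIN_FOOTPRINT whose Tm reaches target."""
    for ln in range(MIN_FOOTPRINT, len(seq) + 1):
        if melting_temperature(seq[:ln]) >= target_tm:
            return ln
    raise DesignError(
        f"{what}: even the full {len(seq)} nt does not reach Tm {target_tm} C")


def _balanced_pair(fwd_side: str, rev_side: str, target_tm: float,
                   tolerance: float, what: str):
    """Footprint lengths with Tm >= target and |Tm_fwd - Tm_rev| <= tolerance.

    Starting from the shortest footprints that individually reach the
    target, both are allowed to grow; the pair with the smallest Tm
    difference (ties: shortest primers) within the search window wins.
    The window widens until the tolerance is met or the fragment is
    exhausted.
    """
    if min(len(fwd_side), len(rev_side)) < MIN_FOOTPRINT:
        raise DesignError(f"{what}: fragment shorter than the minimal "
                          f"{MIN_FOOTPRINT} nt footprint")
    f0 = _footprint_reaching(fwd_side, target_tm, what)
    r0 = _footprint_reaching(rev_side, target_tm, what)
    window = 8
    while True:
        best = None
        for lf in range(f0, min(f0 + window, len(fwd_side)) + 1):
            tf = melting_temperature(fwd_side[:lf])
            for lr in range(r0, min(r0 + window, len(rev_side)) + 1):
                tr = melting_temperature(rev_side[:lr])
                cand = (abs(tf - tr), lf + lr, lf, lr, tf, tr)
                if best is None or cand < best:
                    best = cand
        diff, _, lf, lr, tf, tr = best
        if diff <= tolerance:
            return lf, lr, tf, tr
        exhausted = (f0 + window >= len(fwd_side)
                     and r0 + window >= len(rev_side))
        if exhausted:
            raise DesignError(
                f"{what}: cannot balance footprint Tms within "
                f"{tolerance} C (best difference {diff:.2f} C)")
        window *= 2


def assembly_primers(fragments, vector: AnnotatedMolecule = None,
                     target_tm: float = DEFAULT_TARGET_TM,
                     overlap: int = DEFAULT_OVERLAP,
                     tm_tolerance: float = DEFAULT_TM_TOLERANCE):
    """Design tailed primer pairs for an ordered fragment series.

    Returns one ``(forward Primer, reverse Primer)`` tuple per fragment
    (none for the vector).  Amplifying each fragment with its pair and
    assembling the products -- together with the linearized vector, if one
    was given -- yields a construct in which adjacent sequences share at
    least ``overlap`` identical terminal nucleotides.
    """
    fragments = list(fragments)
    if not fragments:
        raise DesignError("no fragments to design primers for")
    for f in fragments + ([vector] if vector is not None else []):
        if f.circular:
            raise DesignError(f"{f.id} is circular; linearize it first")

    fills = [f.fill() for f in fragments]
    head = overlap // 2          # copied from the upstream fragment's end
    tail_len = overlap - head    # copied from the downstream fragment's start

    pairs = []
    for i, (frag, fill) in enumerate(zip(fragments, fills)):
        lf, lr, tf, tr = _balanced_pair(fill, reverse_complement(fill),
                                        target_tm, tm_tolerance, frag.id)
        fwd_tail = ""
        rev_tail = ""
        if i > 0:
            fwd_tail = fills[i - 1][-head:]
        if i + 1 < len(fragments):
            rev_tail = reverse_complement(fills[i + 1][:tail_len])
        if vector is not None:
            vfill = vector.fill()
            if i == 0:
                fwd_tail = vfill[-overlap:]
            if i == len(fragments) - 1:
                rev_tail = reverse_complement(vfill[:overlap])
        fwd = Primer(f"{frag.id}_fwd", fwd_tail + fill[:lf])
        rev = Primer(f"{frag.id}_rev", rev_tail + reverse_complement(fill)[:lr])
        pairs.append((fwd, rev))
    return pairs
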