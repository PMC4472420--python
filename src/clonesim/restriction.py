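"""Restriction digestion and ligation.

Enzymes are defined by a recognition pattern (IUPAC codes allowed) and a
pair of strand-specific cut offsets; the difference of the offsets gives
the overhang length and sign.  A small table of common enzymes is bundled
as a plain TSV resource (``clonesim/data/enzymes.tsv``) so digestion works
offline; additional enzymes can be registered at runtime with
:func:`register_enzyme`.

Digestion returns fragments in positional order along the parent molecule,
each carrying the sticky or blunt ends implied by the cut geometry.
:func:`ligate` enumerates every product obtainable by joining a small set
of fragments at compatible ends -- the combinatorial idealization of a T4
ligase reaction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .duplex import DuplexSequence, ends_compatible, reverse_complement
from .errors import TopologyError, UniqueSiteError
from .record import AnnotatedMolecule, features_in_window

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_regex(site: str) -> "re.Pattern":
    return re.compile("(?=" + "".join(_IUPAC[c] for c in site) + ")")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition pattern plus strand-specific cut offsets.

    ``watson_cut``/``crick_cut`` are 0-based offsets from the start of the
    recognition site on the watson strand.  BamHI (G^GATCC) is
    ``("BamHI", "GGATCC", 1, 5)``: watson is cut after one base, crick
    after five, leaving a 4-nt 5' overhang (GATC).
    """

    name: str
    site: str
    watson_cut: int
    crick_cut: int

    @property
    def overhang(self) -> int:
        return self.crick_cut - self.watson_cut

    @property
    def site_rc(self) -> str:
        return self.site.translate(_IUPAC_COMPLEMENT)[::-1]

    def __repr__(self) -> str:
        return self.name


@dataclass(frozen=True)
class CutSite:
    """One occurrence of an enzyme's recognition site."""

    enzyme: RestrictionEnzyme
    position: int  # watson coordinate of the watson-strand cut
    strand: int    # +1: site read on watson; -1: site read on crick


def _load_bundled() -> dict:
    table = {}
    text = resources.files("clonesim.data").joinpath("enzymes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, site, wc, cc = line.split("\t")
        table[name] = RestrictionEnzyme(name, site.upper(), int(wc), int(cc))
    return table


ENZYMES: dict = _load_bundled()


def register_enzyme(enzyme: RestrictionEnzyme) -> None:
    """Extension point: make a custom enzyme available by name."""
    ENZYMES[enzyme.name] = enzyme


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return ENZYMES[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; register it first") from None


def _cut_pairs(m: AnnotatedMolecule, e: RestrictionEnzyme):
    """All (watson_cut_col, crick_cut_col, strand, site_start) for ``e``.

    Positions are alignment columns of ``m``; on circular molecules the
    watson cut column is normalised into [0, span).
    """
    f = m.fill()
    span = m.span
    sl = len(e.site)
    if span == 0:
        return []
    text = f + f[:sl - 1] if m.circular else f
    pairs = set()
    for match in _iupac_regex(e.site).finditer(text):
        p = match.start()
        pairs.add((p + e.watson_cut, p + e.crick_cut, 1, p))
    if e.site_rc != e.site:
        for match in _iupac_regex(e.site_rc).finditer(text):
            p = match.start()
            pairs.add((p + sl - e.crick_cut, p + sl - e.watson_cut, -1, p))
    out = []
    seen = set()
    for w, c, strand, p in pairs:
        if m.circular:
            shiftb = w % span - w
            w, c, p = w + shiftb, c + shiftb, p + shiftb
        else:
            if not (0 <= w <= span and 0 <= c <= span):
                continue  # cut would fall outside the molecule
        key = (w, c)
        if key in seen:
            continue  # palindromic site found on both strands
        seen.add(key)
        out.append((w, c, strand, p))
    out.sort()
    return out


def find_sites(m: AnnotatedMolecule, e: RestrictionEnzyme):
    """All recognition sites of ``e`` in ``m``, sorted by cut position."""
    return [CutSite(e, w, strand) for w, c, strand, p in _cut_pairs(m, e)]


def _fragment_linear(m, w1, c1, w2, c2):
    seq = m.seq
    ws, cs = seq._wstart, seq._cstart
    we, ce = ws + len(seq.watson), cs + len(seq.crick)
    wa, wb = max(w1, ws), min(w2, we)
    ca, cb = max(c1, cs), min(c2, ce)
    watson = seq.watson[wa - ws:wb - ws]
    crick = seq.crick[ce - cb:ce - ca]
    frag = DuplexSequence(watson, crick, wa - ca, False)
    col0 = min(wa, ca)
    feats = features_in_window(m.features, col0, frag.span, m.span, False)
    return AnnotatedMolecule(frag, id=m.id, name=m.name,
                             description=m.description, features=feats,
                             annotations=dict(m.annotations))


def _fragment_circular(m, w1, c1, w2, c2):
    f = m.fill()
    span = m.span
    t = f * 3  # generous window; all indices shifted by +span
    watson = t[span + w1:span + w2]
    crick = reverse_complement(t[span + c1:span + c2])
    frag = DuplexSequence(watson, crick, w1 - c1, False)
    col0 = min(w1, c1) % span
    feats = features_in_window(m.features, col0, frag.span, span, True)
    return AnnotatedMolecule(frag, id=m.id, name=m.name,
                             description=m.description, features=feats,
                             annotations=dict(m.annotations))


def cut(m: AnnotatedMolecule, *enzymes: RestrictionEnzyme):
    """Digest ``m`` with one or more enzymes.

    Returns fragments in positional order.  A linear molecule with n cuts
    yields n+1 fragments (the uncut molecule itself for n = 0); a circular
    molecule with n >= 1 cuts yields n linear fragments, and an empty list
    when no enzyme cuts.
    """
    pairs = []
    for e in enzymes:
        pairs.extend((w, c) for w, c, s, p in _cut_pairs(m, e))
    pairs = sorted(set(pairs))
    if not pairs:
        return [] if m.circular else [m.copy()]
    if m.circular:
        frags = []
        for i, (w1, c1) in enumerate(pairs):
            if i + 1 < len(pairs):
                w2, c2 = pairs[i + 1]
            else:
                w2, c2 = pairs[0][0] + m.span, pairs[0][1] + m.span
            frags.append(_fragment_circular(m, w1, c1, w2, c2))
        return frags
    seq = m.seq
    bounds = ([(seq._wstart, seq._cstart)] + pairs
              + [(seq._wstart + len(seq.watson), seq._cstart + len(seq.crick))])
    return [_fragment_linear(m, w1, c1, w2, c2)
            for (w1, c1), (w2, c2) in zip(bounds, bounds[1:])]


def linearize(m: AnnotatedMolecule, e: RestrictionEnzyme) -> AnnotatedMolecule:
    """Open a circular molecule at the unique site of ``e``."""
    if not m.circular:
        raise TopologyError("linearize() expects a circular molecule")
    frags = cut(m, e)
    if len(frags) != 1:
        raise UniqueSiteError(
            f"{e.name} cuts {m.id} {len(frags)} times; need exactly one site")
    return frags[0]


def ligate(fragments, max_fragments: int = 8):
    """All distinct ligation products of a set of linear fragments.

    Every fragment is used at most once, in either orientation.  Sticky
    joins require exactly complementary overhangs; blunt joins blunt.
    Both circular closures (including single-fragment self-circularization)
    and linear chains of two or more fragments are returned, deduplicated
    by canonical form and sorted by descending span.  Joining a fragment
    head-to-head with a second copy of itself is impossible by
    construction, since each input participates at most once.

    The enumeration is combinatorial and intended for the small fragment
    sets of real cloning steps; ``max_fragments`` guards against explosion.
    """
    fragments = list(fragments)
    if not fragments:
        return []
    if len(fragments) > max_fragments:
        raise ValueError(
            f"ligate() is combinatorial; refusing {len(fragments)} fragments "
            f"(max_fragments={max_fragments})")
    for f in fragments:
        if f.circular:
            raise TopologyError("ligate() expects linear fragments")

    products = {}

    def _add(mol):
        key = (mol.circular, mol.canonical_form())
        products.setdefault(key, mol)

    oriented = []
    for i, f in enumerate(fragments):
        oriented.append((i, f))
        oriented.append((i, f.reverse_complement()))

    def _extend(chain_mol, used, depth):
        if depth >= 2:
            _add(chain_mol)
        if ends_compatible(chain_mol.seq.right_end(), chain_mol.seq.left_end()):
            _add(chain_mol.looped())
        for j, cand in oriented:
            if j in used:
                continue
            if ends_compatible(chain_mol.seq.right_end(), cand.seq.left_end()):
                _extend(chain_mol.join(cand), used | {j}, depth + 1)

    for i, f in oriented:
        _extend(f, {i}, 1)

    out = list(products.values())
    out.sort(key=lambda m: (-m.span, m.canonical_form()))
    return out
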