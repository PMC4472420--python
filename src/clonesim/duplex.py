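"""Double-stranded DNA model with sticky ends and topology.

A :class:`DuplexSequence` stores the two antiparallel strands of a DNA
duplex explicitly, together with an integer *stagger* describing how the
strands are aligned against each other.  This is the minimal amount of
state needed to simulate cohesive ("sticky") ends left by restriction
enzymes, their ligation, and circular topology.

Alignment-column convention
---------------------------
Picture the molecule drawn the usual way: the watson strand 5'->3' left
to right on top, the crick strand (written 5'->3' in its own field)
antiparallel underneath.  Columns are numbered 0..span-1 left to right.

``stagger`` is the number of columns by which the crick strand's 3'
terminus extends to the left of the watson 5' terminus:

* ``stagger > 0`` -- crick protrudes on the left,
* ``stagger < 0`` -- watson protrudes on the left (e.g. the 5'-GATC
  overhang left by BamHI/BglII),
* ``stagger == 0`` -- flush on the left.

The *span* of a molecule is the number of alignment columns covered by
either strand.  A blunt or circular molecule's span equals its strand
length; a fragment with a 4-nt overhang at each end cut from a 9637 bp
circle spans 9641 columns, which is the length a gel would show.
"""

from __future__ import annotations

from .errors import IncompatibleEndsError, TopologyError

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

BLUNT = "blunt"
FIVE_PRIME = "5'"
THREE_PRIME = "3'"


def complement(s: str) -> str:
    """Complement of a nucleotide string (same orientation)."""
    return s.translate(_COMPLEMENT)


def reverse_complement(s: str) -> str:
    """Reverse complement of a nucleotide string."""
    return s.translate(_COMPLEMENT)[::-1]


def _check_alphabet(s: str, what: str) -> str:
    s = s.upper()
    if s.strip("ACGT"):
        bad = sorted(set(s) - set("ACGT"))
        raise ValueError(f"{what} contains non-ACGT characters: {bad}")
    return s


def least_rotation(s: str) -> str:
    """Lexicographically least rotation of ``s`` (Booth's algorithm, O(n))."""
    if not s:
        return s
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k:k + len(s)]


class DuplexSequence:
    """Two antiparallel strands with an explicit stagger and topology.

    Parameters
    ----------
    watson : str
        Sense strand, 5'->3'.
    crick : str
        Complementary strand, 5'->3' (i.e. as it would be sequenced, not
        as it is drawn under watson).
    stagger : int
        Left-end alignment offset; see module docstring.
    circular : bool
        Closed-circle topology.  Implies ``stagger == 0`` and strands of
        equal length (a circle has no ends, hence no overhangs).
    """

    __slots__ = ("watson", "crick", "stagger", "circular")

    def __init__(self, watson: str, crick: str, stagger: int = 0,
                 circular: bool = False):
        self.watson = _check_alphabet(watson, "watson strand")
        self.crick = _check_alphabet(crick, "crick strand")
        self.stagger = int(stagger)
        self.circular = bool(circular)
        self._validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_string(cls, seq: str, circular: bool = False) -> "DuplexSequence":
        """Blunt (or circular) duplex from a single watson-strand string."""
        seq = _check_alphabet(seq, "sequence")
        return cls(seq, reverse_complement(seq), 0, circular)

    # -- geometry -------------------------------------------------------------

    @property
    def _wstart(self) -> int:
        return max(self.stagger, 0)

    @property
    def _cstart(self) -> int:
        return max(-self.stagger, 0)

    @property
    def span(self) -> int:
        """Number of alignment columns covered by either strand."""
        return max(self._wstart + len(self.watson),
                   self._cstart + len(self.crick))

    def __len__(self) -> int:
        return self.span

    @property
    def right_stagger(self) -> int:
        """Columns by which crick's 5' end extends right of watson's 3' end."""
        return (self._cstart + len(self.crick)) - (self._wstart + len(self.watson))

    def _validate(self) -> None:
        if self.circular:
            if self.stagger != 0 or len(self.watson) != len(self.crick):
                raise ValueError("a circular molecule cannot carry overhangs")
        if not self.watson and not self.crick:
            if self.stagger:
                raise ValueError("empty molecule must have zero stagger")
            return
        ws, cs = self._wstart, self._cstart
        a = max(ws, cs)
        b = min(ws + len(self.watson), cs + len(self.crick))
        if b - a < 1 and (self.watson and self.crick):
            raise ValueError("strands do not overlap; not a duplex")
        # complementarity over the double-stranded region
        w_part = self.watson[a - ws:b - ws]
        c_part = reverse_complement(self.crick)[a - cs:b - cs]
        if w_part != c_part:
            raise ValueError("strands are not complementary where annealed")

    # -- derived sequences ----------------------------------------------------

    def fill(self) -> str:
        """Watson-sense sequence over all span columns.

        Columns covered only by the crick strand are filled in with the
        complement, i.e. the sequence a polymerase fill-in would produce.
        """
        cols = [""] * self.span
        ws = self._wstart
        for i, base in enumerate(self.watson):
            cols[ws + i] = base
        cs = self._cstart
        csense = reverse_complement(self.crick)
        for i, base in enumerate(csense):
            if not cols[cs + i]:
                cols[cs + i] = base
        return "".join(cols)

    # -- ends -----------------------------------------------------------------

    def left_end(self) -> tuple:
        """The left end as ``(kind, sequence)``.

        ``kind`` is one of ``"blunt"``, ``"5'"`` or ``"3'"``; the sequence
        is the protruding single strand read 5'->3' on its own strand.
        """
        if self.circular:
            raise TopologyError("a circular molecule has no ends")
        s = self.stagger
        if s == 0:
            return (BLUNT, "")
        if s < 0:  # watson protrudes at its 5' terminus
            return (FIVE_PRIME, self.watson[:-s])
        return (THREE_PRIME, self.crick[len(self.crick) - s:])

    def right_end(self) -> tuple:
        if self.circular:
            raise TopologyError("a circular molecule has no ends")
        r = self.right_stagger
        if r == 0:
            return (BLUNT, "")
        if r > 0:  # crick protrudes at its 5' terminus
            return (FIVE_PRIME, self.crick[:r])
        return (THREE_PRIME, self.watson[r:])

    # -- operations -----------------------------------------------------------

    def reverse_complement(self) -> "DuplexSequence":
        """The molecule viewed from the other face (strands swap roles)."""
        if self.circular:
            return DuplexSequence(self.crick, self.watson, 0, True)
        return DuplexSequence(self.crick, self.watson, -self.right_stagger, False)

    def shift(self, n: int) -> "DuplexSequence":
        """Rotate the origin of a circular molecule by ``n`` columns."""
        if not self.circular:
            raise TopologyError("shift() applies to circular molecules only")
        if self.span == 0:
            return self
        n %= self.span
        w = self.watson[n:] + self.watson[:n]
        return DuplexSequence(w, reverse_complement(w), 0, True)

    def join(self, other: "DuplexSequence") -> "DuplexSequence":
        """Ligate ``other`` onto this molecule's right end."""
        if self.circular or other.circular:
            raise TopologyError("only linear molecules can be joined")
        if not ends_compatible(self.right_end(), other.left_end()):
            raise IncompatibleEndsError(
                f"cannot join {self.right_end()} to {other.left_end()}")
        return DuplexSequence(self.watson + other.watson,
                              other.crick + self.crick,
                              self.stagger, False)

    def looped(self) -> "DuplexSequence":
        """Circularize a linear molecule whose two ends are compatible."""
        if self.circular:
            raise TopologyError("molecule is already circular")
        if not ends_compatible(self.right_end(), self.left_end()):
            raise IncompatibleEndsError(
                f"ends {self.left_end()} / {self.right_end()} cannot ligate")
        o = abs(self.stagger)
        f = self.fill()
        w = f[:self.span - o]
        return DuplexSequence(w, reverse_complement(w), 0, True)

    def canonical_form(self) -> str:
        """Rotation- and strand-invariant key identifying the physical DNA.

        Circular molecules: the lexicographically least rotation over the
        watson strand and its reverse complement.  Linear molecules: the
        lesser of the filled sequence and its reverse complement.  Two
        molecules of equal topology represent the same physical DNA iff
        their canonical forms are equal.
        """
        f = self.fill()
        if self.circular:
            return min(least_rotation(f), least_rotation(reverse_complement(f)))
        return min(f, reverse_complement(f))

    # -- dunder ---------------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, DuplexSequence):
            return NotImplemented
        if self.circular != other.circular:
            return False
        if self.circular:
            return self.canonical_form() == other.canonical_form()
        return (self.watson == other.watson and self.crick == other.crick
                and self.stagger == other.stagger)

    def __hash__(self) -> int:
        return hash((self.circular, self.canonical_form()))

    def __repr__(self) -> str:
        tag = "o" if self.circular else "-"
        return f"DuplexSequence({tag}{self.span})"


def ends_compatible(right: tuple, left: tuple) -> bool:
    """Can a molecule's *right* end ligate to another's *left* end?

    Blunt joins blunt; sticky ends must be the same kind (both 5' or both
    3') and the two single strands must anneal exactly, i.e. one overhang
    is the reverse complement of the other.  GATC/GATC (BamHI x BglII)
    satisfies this because GATC is self-complementary.
    """
    rk, rs = right
    lk, ls = left
    if rk == BLUNT and lk == BLUNT:
        return True
    if rk != lk:
        return False
    return ls == reverse_complement(rs)
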