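"""Annotated molecules: a duplex plus identity, features and metadata.

:class:`AnnotatedMolecule` is the universal currency of every simulated
unit operation in this package -- digestion, ligation, PCR and assembly
all consume and produce annotated molecules, so a cloning strategy can be
written as a chain of ordinary function calls and every intermediate
inspected.

Coordinates are 0-based, half-open, on the watson strand.  On circular
molecules a feature that spans the origin is stored with ``start > end``
and interpreted modulo the span.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .duplex import DuplexSequence, reverse_complement
from .errors import TopologyError


@dataclass
class Feature:
    """A GenBank-style annotation anchored on the watson strand."""

    kind: str
    start: int
    end: int
    strand: int = 1
    qualifiers: dict = field(default_factory=dict)

    def length(self, span: int) -> int:
        if self.start <= self.end:
            return self.end - self.start
        return span - self.start + self.end  # wraps the origin

    def validate(self, span: int, circular: bool) -> None:
        if not circular:
            if not (0 <= self.start <= self.end <= span):
                raise ValueError(
                    f"feature [{self.start},{self.end}) outside linear span {span}")
        else:
            if not (0 <= self.start <= span and 0 <= self.end <= span):
                raise ValueError(
                    f"feature [{self.start},{self.end}) outside circular span {span}")

    def copy(self) -> "Feature":
        return Feature(self.kind, self.start, self.end, self.strand,
                       copy.deepcopy(self.qualifiers))


def features_in_window(features, w_start: int, w_len: int, span: int,
                       circular: bool):
    """Features fully contained in a window, re-anchored to window coords.

    The window starts at column ``w_start`` of the parent molecule and is
    ``w_len`` columns long; on a circular parent it may wrap the origin.
    Features that cross either window boundary are dropped -- the same
    containment rule PCR uses for carrying template features into the
    amplicon.
    """
    kept = []
    for f in features:
        flen = f.length(span)
        if circular:
            off = (f.start - w_start) % span
        else:
            off = f.start - w_start
        if off < 0 or off + flen > w_len:
            continue
        kept.append(Feature(f.kind, off, off + flen, f.strand,
                            copy.deepcopy(f.qualifiers)))
    return kept


class AnnotatedMolecule:
    """A :class:`DuplexSequence` with identity, features and metadata."""

    def __init__(self, seq: DuplexSequence, id: str = "id", name: str = "",
                 description: str = "", features=None, annotations=None):
        self.seq = seq
        self.id = id
        self.name = name or id
        self.description = description
        self.features = list(features or [])
        self.annotations = dict(annotations or {})
        self._validate_features()

    # -- construction ----------------------------------------------------------

    @classmethod
    def from_string(cls, sequence: str, circular: bool = False, id: str = "id",
                    **kw) -> "AnnotatedMolecule":
        return cls(DuplexSequence.from_string(sequence, circular), id=id, **kw)

    def _validate_features(self) -> None:
        for f in self.features:
            f.validate(self.span, self.circular)

    def _replace(self, seq: DuplexSequence, features) -> "AnnotatedMolecule":
        return AnnotatedMolecule(seq, id=self.id, name=self.name,
                                 description=self.description,
                                 features=features,
                                 annotations=dict(self.annotations))

    def copy(self) -> "AnnotatedMolecule":
        return self._replace(self.seq, [f.copy() for f in self.features])

    # -- delegated geometry ----------------------------------------------------

    @property
    def circular(self) -> bool:
        return self.seq.circular

    @property
    def span(self) -> int:
        return self.seq.span

    def __len__(self) -> int:
        return self.seq.span

    def fill(self) -> str:
        return self.seq.fill()

    def canonical_form(self) -> str:
        return self.seq.canonical_form()

    def short_repr(self) -> str:
        """Compact topology/length tag: ``o9637`` circular, ``-330`` linear."""
        return ("o" if self.circular else "-") + str(self.span)

    def __repr__(self) -> str:
        return f"AnnotatedMolecule({self.id} {self.short_repr()})"

    # -- operations ------------------------------------------------------------

    def reverse_complement(self) -> "AnnotatedMolecule":
        span = self.span
        new_feats = []
        for f in self.features:
            flen = f.length(span)
            if self.circular:
                ns = (span - f.end) % span
                ne = ns + flen
                if ne > span:
                    ne -= span  # still wraps after mirroring
            else:
                ns, ne = span - f.end, span - f.start
            new_feats.append(Feature(f.kind, ns, ne, -f.strand,
                                     copy.deepcopy(f.qualifiers)))
        return self._replace(self.seq.reverse_complement(), new_feats)

    def __getitem__(self, item) -> "AnnotatedMolecule":
        if not isinstance(item, slice) or item.step not in (None, 1):
            raise TypeError("molecules support contiguous slices only")
        if self.circular:
            raise TopologyError(
                "cannot slice a circular molecule; shift() or linearize first")
        span = self.span
        start, stop, _ = item.indices(span)
        if stop < start:
            stop = start
        return self.slice(start, stop)

    def slice(self, start: int, stop: int) -> "AnnotatedMolecule":
        """Blunt sub-molecule of columns [start, stop) of a linear molecule.

        Overhang columns inside the window are filled in, so the result is
        always blunt.  Features fully inside the window are kept and
        shifted; features crossing a boundary are dropped.
        """
        if self.circular:
            raise TopologyError(
                "cannot slice a circular molecule; shift() or linearize first")
        span = self.span
        if start < 0:
            start += span
        if stop < 0:
            stop += span
        if not (0 <= start <= stop <= span):
            raise IndexError(f"slice [{start}:{stop}] outside span {span}")
        sub = self.fill()[start:stop]
        feats = features_in_window(self.features, start, stop - start,
                                   span, False)
        return self._replace(DuplexSequence.from_string(sub), feats)

    def shift(self, n: int) -> "AnnotatedMolecule":
        """Rotate the origin of a circular molecule by ``n`` columns."""
        if not self.circular:
            raise TopologyError("shift() applies to circular molecules only")
        span = self.span
        if span == 0:
            return self.copy()
        n %= span
        feats = []
        for f in self.features:
            flen = f.length(span)
            ns = (f.start - n) % span
            ne = (f.end - n) % span
            if ne == 0 and flen > 0:
                ne = span  # touches, but does not cross, the new origin
            feats.append(Feature(f.kind, ns, ne, f.strand,
                                 copy.deepcopy(f.qualifiers)))
        return self._replace(self.seq.shift(n), feats)

    def looped(self) -> "AnnotatedMolecule":
        """Circularize; ends must be ligation-compatible (see duplex layer)."""
        new_seq = self.seq.looped()
        new_span = new_seq.span
        feats = [f.copy() for f in self.features
                 if f.start <= f.end and f.end <= new_span]
        return self._replace(new_seq, feats)

    def join(self, other: "AnnotatedMolecule") -> "AnnotatedMolecule":
        """Ligate ``other`` onto this molecule's right end (sticky or blunt)."""
        new_seq = self.seq.join(other.seq)
        offset = new_seq.span - other.span
        feats = [f.copy() for f in self.features]
        for f in other.features:
            g = f.copy()
            g.start += offset
            g.end += offset
            feats.append(g)
        out = self._replace(new_seq, feats)
        out.id = f"{self.id}+{other.id}"
        out.name = out.id
        return out
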