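"""Reading, writing and cached retrieval of sequence records.

GenBank and FASTA parsing/serialization is delegated to Biopython's
``SeqIO``; this module converts between ``SeqRecord`` and the package's
:class:`~clonesim.record.AnnotatedMolecule`, taking the topology from the
LOCUS line (absent token = linear) and preserving feature keys and
qualifiers verbatim.

GenBank cannot represent sticky ends, so writing a sticky-ended molecule
fills the overhangs (blunts it) and notes that in a comment annotation.
Serialization is deterministic: the LOCUS date is pinned unless the
molecule carries one, so identical molecules produce identical files.

:func:`fetch_genbank` downloads a record once into a local cache
directory and afterwards serves it from the cache, which is how scripted
cloning strategies stay reproducible and runnable offline.
"""

from __future__ import annotations

import io as _io
import os
import urllib.error
import urllib.request
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .duplex import DuplexSequence
from .errors import FetchError, ParseError
from .record import AnnotatedMolecule, Feature

_EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
           "?db=nucleotide&id={acc}&rettype=gbwithparts&retmode=text")
_PINNED_DATE = "01-JAN-1980"  # deterministic output for undated molecules
CACHE_ENV = "CLONESIM_CACHE"


def default_cache_dir() -> Path:
    return Path(os.environ.get(CACHE_ENV,
                               Path.home() / ".cache" / "clonesim"))


# ---------------------------------------------------------------------------
# SeqRecord conversion
# ---------------------------------------------------------------------------

def _from_seqrecord(rec: SeqRecord) -> AnnotatedMolecule:
    circular = rec.annotations.get("topology", "linear") == "circular"
    seq = str(rec.seq).upper()
    span = len(seq)
    feats = []
    for sf in rec.features:
        strand = sf.location.strand or 1
        parts = sorted(sf.location.parts, key=lambda p: int(p.start))
        start = int(sf.location.parts[0].start)
        end = int(sf.location.parts[-1].end)
        if circular and len(parts) == 2 and int(parts[0].start) == 0 \
                and int(parts[-1].end) == span:
            # origin-spanning join(a..span,1..b): store wrapped
            start, end = int(parts[-1].start), int(parts[0].end)
        quals = {k: list(v) for k, v in sf.qualifiers.items()}
        feats.append(Feature(sf.type, start, end, strand, quals))
    annotations = {k: v for k, v in rec.annotations.items()}
    return AnnotatedMolecule(DuplexSequence.from_string(seq, circular),
                             id=rec.id, name=rec.name,
                             description=rec.description,
                             features=feats, annotations=annotations)


def _to_seqrecord(m: AnnotatedMolecule) -> SeqRecord:
    annotations = dict(m.annotations)
    annotations["molecule_type"] = annotations.get("molecule_type", "DNA")
    annotations["topology"] = "circular" if m.circular else "linear"
    annotations.setdefault("date", _PINNED_DATE)
    if not m.circular and m.seq.stagger == 0 and m.seq.right_stagger == 0:
        pass
    elif not m.circular:
        annotations["comment"] = (annotations.get("comment", "")
                                  + "sticky ends blunted for GenBank export"
                                  ).strip()
    rec = SeqRecord(Seq(m.fill()), id=m.id, name=(m.name or m.id)[:16],
                    description=m.description, annotations=annotations)
    span = m.span
    for f in m.features:
        if f.start <= f.end:
            loc = SimpleLocation(f.start, f.end, strand=f.strand)
        else:  # origin-spanning feature on a circle
            loc = CompoundLocation([
                SimpleLocation(f.start, span, strand=f.strand),
                SimpleLocation(0, f.end, strand=f.strand)])
        rec.features.append(SeqFeature(loc, type=f.kind,
                                       qualifiers={k: list(v) for k, v
                                                   in f.qualifiers.items()}))
    return rec


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def read_genbank(source) -> AnnotatedMolecule:
    """Read one GenBank record from a path, file object or flat-file text."""
    text = None
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.lstrip().startswith("LOCUS"):
            text = s
        else:
            try:
                text = Path(s).read_text()
            except OSError as exc:
                raise ParseError(f"cannot read {s!r}: {exc}") from exc
    try:
        rec = SeqIO.read(_io.StringIO(text), "genbank")
    except ValueError as exc:
        head = text.strip().splitlines()[:1]
        raise ParseError(
            f"malformed GenBank record (near {head!r}): {exc}") from exc
    return _from_seqrecord(rec)


def write_genbank(m: AnnotatedMolecule, path) -> None:
    """Serialize one molecule as a GenBank flat file (deterministic)."""
    rec = _to_seqrecord(m)
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "genbank")


def genbank_text(m: AnnotatedMolecule) -> str:
    buf = _io.StringIO()
    SeqIO.write([_to_seqrecord(m)], buf, "genbank")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source):
    """All records of a FASTA file as blunt linear molecules."""
    if hasattr(source, "read"):
        handle = _io.StringIO(source.read())
    else:
        s = str(source)
        handle = _io.StringIO(s) if s.lstrip().startswith(">") \
            else _io.StringIO(Path(s).read_text())
    out = []
    for rec in SeqIO.parse(handle, "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(AnnotatedMolecule(
            DuplexSequence.from_string(str(rec.seq)),
            id=rec.id, description=desc))
    return out


def write_fasta(molecules, path) -> None:
    recs = [SeqRecord(Seq(m.fill()), id=m.id,
                      description=m.description) for m in molecules]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# Cached GenBank retrieval
# ---------------------------------------------------------------------------

def fetch_genbank(accession: str, cache_dir=None) -> AnnotatedMolecule:
    """Fetch a nucleotide record by accession, caching the flat file.

    The first call downloads the record into ``cache_dir`` (default:
    ``$CLONESIM_CACHE`` or ``~/.cache/clonesim``); later calls -- and
    offline runs -- are served from the cache.  The cache is keyed by the
    accession string; records are assumed stable over time.
    """
    if not accession or any(c in accession for c in "/\\ "):
        raise FetchError(f"invalid accession {accession!r}")
    cache = Path(cache_dir) if cache_dir else default_cache_dir()
    cached = cache / f"{accession}.gb"
    if cached.exists():
        return read_genbank(cached)
    url = _EFETCH.format(acc=accession)
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:
            text = resp.read().decode()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(
            f"accession {accession} is not cached under {cache} and could "
            f"not be downloaded ({exc}); run once with network access or "
            f"place the flat file there") from exc
    if not text.lstrip().startswith("LOCUS"):
        raise FetchError(f"no GenBank record returned for {accession}")
    cache.mkdir(parents=True, exist_ok=True)
    cached.write_text(text)
    return read_genbank(cached)
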