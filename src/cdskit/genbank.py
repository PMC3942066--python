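"""GenBank flat-file ingestion.

Parses release-format GenBank flat files into :class:`CDSRecord` objects,
one per annotated CDS feature that carries a ``/translation`` qualifier.
Pseudo genes and translation-less CDS are skipped (and counted).  The
location parser understands the subset of the GenBank location language
used by ordinary CDS annotation: positions, ``..`` ranges, ``join()``,
``complement()`` and the ``<`` / ``>`` partial-end markers.  ``order()``,
``bond()`` and mixed-strand joins are rejected: trans-spliced genes are
out of scope, and the ``/translation`` qualifier is authoritative (no
on-the-fly translation is attempted).

Coordinates are 1-based inclusive throughout, the GenBank convention.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import IO, Iterator, Optional

logger = logging.getLogger(__name__)

# 20 standard amino acids; anything else in a protein is "ambiguous"
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
# unambiguous nucleotides; anything else in DNA is "ambiguous"
STANDARD_NT = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class GenBankParseError(ValueError):
    """Raised for malformed flat files or unsupported location strings."""


@dataclass
class FeatureLocation:
    """A parsed CDS location.

    ``intervals`` are (start, end, strand) triples, 1-based inclusive,
    listed in *coding* order (for a ``complement()`` location the
    interval order given in the flat file is reversed so that the first
    interval contains the 5' end of the coding sequence).  ``left_open``
    and ``right_open`` record the ``<`` / ``>`` markers on the leftmost
    and rightmost *genomic* coordinates; their mapping onto 5'/3'
    incompleteness is strand-dependent (see :func:`partial_flags`).
    """

    intervals: list[tuple[int, int, int]]
    left_open: bool = False
    right_open: bool = False

    @property
    def strand(self) -> int:
        return self.intervals[0][2]

    @property
    def span(self) -> int:
        return sum(end - start + 1 for start, end, _ in self.intervals)


_INTERVAL_RE = re.compile(r"^(<?)(\d+)(?:\.\.(>?)(\d+))?$")


def _parse_simple(text: str) -> tuple[int, int, bool, bool]:
    """One interval: ``10..20``, ``<10..20``, ``10..>20`` or a bare position."""
    m = _INTERVAL_RE.match(text)
    if not m:
        raise GenBankParseError(f"unsupported location element: {text!r}")
    lt, start_s, gt, end_s = m.groups()
    start = int(start_s)
    end = int(end_s) if end_s is not None else start
    if start > end:
        raise GenBankParseError(f"interval start > end in {text!r}")
    return start, end, bool(lt), bool(gt)


def _split_args(text: str) -> list[str]:
    """Split a join() argument list on top-level commas."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return [p.strip() for p in parts]


def parse_location(text: str) -> FeatureLocation:
    """Parse a GenBank location expression into a :class:`FeatureLocation`.

    ``complement()`` flips the strand and reverses interval order to
    coding order.  A ``join()`` whose elements are *all* complemented is
    accepted as a minus-strand location; mixing strands within one join
    is rejected, as are ``order()`` and ``bond()`` operators.
    """
    text = text.strip().replace(" ", "")
    if not text:
        raise GenBankParseError("empty location")
    for op in ("order(", "bond("):
        if op in text:
            raise GenBankParseError(f"unsupported operator in location {text!r}")
    return _parse_loc(text)


def _parse_loc(text: str) -> FeatureLocation:
    if text.startswith("complement(") and text.endswith(")"):
        inner = _parse_loc(text[len("complement("):-1])
        intervals = [(s, e, -st) for s, e, st in reversed(inner.intervals)]
        return FeatureLocation(intervals, inner.left_open, inner.right_open)
    if text.startswith("join(") and text.endswith(")"):
        parts = [_parse_loc(p) for p in _split_args(text[len("join("):-1])]
        if not parts:
            raise GenBankParseError(f"empty join in {text!r}")
        strands = {p.strand for p in parts}
        if len(strands) != 1:
            raise GenBankParseError(f"mixed-strand join rejected: {text!r}")
        strand = strands.pop()
        # join elements are listed in coding order in both forms:
        # plus-strand joins in genomic order, and joins of complement()
        # elements with the downstream (coding-first) exon first
        intervals = [iv for p in parts for iv in p.intervals]
        if strand == 1:
            _check_markers(parts)
            left_open = parts[0].left_open
            right_open = parts[-1].right_open
        else:
            # genomic leftmost coordinate lives in the last coding element
            for i, p in enumerate(parts):
                if p.left_open and i != len(parts) - 1:
                    raise GenBankParseError("interior '<' marker in join")
                if p.right_open and i != 0:
                    raise GenBankParseError("interior '>' marker in join")
            left_open = parts[-1].left_open
            right_open = parts[0].right_open
        return FeatureLocation(intervals, left_open, right_open)
    start, end, lt, gt = _parse_simple(text)
    return FeatureLocation([(start, end, 1)], lt, gt)


def _check_markers(parts: list[FeatureLocation]) -> None:
    # open-end markers only make sense on the outermost coordinates
    for i, p in enumerate(parts):
        if p.left_open and i != 0:
            raise GenBankParseError("interior '<' marker in join")
        if p.right_open and i != len(parts) - 1:
            raise GenBankParseError("interior '>' marker in join")


def partial_flags(loc: FeatureLocation) -> tuple[bool, bool]:
    """Map the genomic-coordinate open-end markers to (partial5, partial3).

    On the plus strand the genomic left end is the 5' end, so
    ``partial5 = left_open``; on the minus strand the mapping swaps.
    """
    if loc.strand >= 0:
        return loc.left_open, loc.right_open
    return loc.right_open, loc.left_open


def sequence_md5(seq: str) -> str:
    """MD5 of the uppercased, whitespace-stripped sequence.

    Lookup by hash is case-insensitive but otherwise exact; trailing
    stop characters ``*`` are stripped so that proteins written with and
    without an explicit stop hash identically.
    """
    clean = "".join(seq.split()).upper().rstrip("*")
    if not clean:
        raise ValueError("cannot hash an empty sequence")
    return hashlib.md5(clean.encode("ascii")).hexdigest()


def percent_gc(dna: str) -> float:
    """Percent G+C of a nucleotide string.

    ``S`` (strong, G or C) counts toward the numerator; all other
    ambiguity codes count in the denominator only.
    """
    if not dna:
        raise ValueError("cannot compute GC of an empty sequence")
    up = dna.upper()
    gc = sum(up.count(c) for c in "GCS")
    return 100.0 * gc / len(up)


_REFSEQ_RE = re.compile(r"^[A-Z]{2,}_\d+")


def is_refseq(accession: str) -> bool:
    """RefSeq accessions carry an underscore (NP_, XP_, YP_, WP_, ...)."""
    return bool(_REFSEQ_RE.match(accession or ""))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def splice(origin: str, loc: FeatureLocation) -> str:
    """Extract the coding-strand CDS sequence from the entry sequence.

    ``origin`` is the full plus-strand entry sequence.  Intervals are in
    coding order; minus-strand slices are reverse-complemented.
    """
    parts = []
    n = len(origin)
    for start, end, strand in loc.intervals:
        if end > n:
            raise GenBankParseError(
                f"location interval {start}..{end} beyond sequence length {n}"
            )
        chunk = origin[start - 1 : end]
        parts.append(reverse_complement(chunk) if strand < 0 else chunk)
    return "".join(parts).upper()


@dataclass
class CDSRecord:
    """One annotated coding sequence: DNA + protein, hashes, flags, provenance."""

    protein_accession: str
    source_accession: str
    taxon_id: Optional[int]
    organism: str
    dna_seq: str
    aa_seq: str
    location: Optional[FeatureLocation] = None
    gi: Optional[int] = None
    gene: Optional[str] = None
    product: Optional[str] = None
    locus_tag: Optional[str] = None
    note: Optional[str] = None
    codon_start: int = 1
    transl_table: int = 1
    partial5: bool = False
    partial3: bool = False
    source_length: int = 0
    entry_date: Optional[date] = None
    dna_md5: str = field(default="")
    prot_md5: str = field(default="")
    is_refseq: bool = field(default=False)
    cds_length: int = field(default=0)
    pcGC: float = field(default=0.0)
    passthrough: bool = False

    def __post_init__(self) -> None:
        if self.dna_seq:
            self.dna_seq = self.dna_seq.upper()
            if not self.dna_md5:
                self.dna_md5 = sequence_md5(self.dna_seq)
            self.cds_length = len(self.dna_seq)
            self.pcGC = round(percent_gc(self.dna_seq), 2)
        if self.aa_seq:
            self.aa_seq = self.aa_seq.upper().rstrip("*")
            if not self.prot_md5:
                self.prot_md5 = sequence_md5(self.aa_seq)
        self.is_refseq = is_refseq(self.protein_accession)

    @property
    def dna_ambiguous(self) -> bool:
        return bool(self.dna_seq) and any(c not in STANDARD_NT for c in self.dna_seq)

    @property
    def aa_ambiguous(self) -> bool:
        return bool(self.aa_seq) and any(c not in STANDARD_AA for c in self.aa_seq)


@dataclass
class IngestReport:
    entries_read: int = 0
    cds_kept: int = 0
    pseudo_skipped: int = 0
    no_translation_skipped: int = 0
    entries_without_sequence: int = 0


_MONTHS = {
    "JAN": 1, "FEB": 2, "MAR": 3, "APR": 4, "MAY": 5, "JUN": 6,
    "JUL": 7, "AUG": 8, "SEP": 9, "OCT": 10, "NOV": 11, "DEC": 12,
}


def _parse_locus_date(line: str) -> Optional[date]:
    m = re.search(r"(\d{2})-([A-Z]{3})-(\d{4})\s*$", line)
    if not m:
        return None
    day, mon, year = m.groups()
    try:
        return date(int(year), _MONTHS[mon], int(day))
    except (KeyError, ValueError):
        return None


class _Feature:
    __slots__ = ("key", "location_text", "qualifiers")

    def __init__(self, key: str, location_text: str):
        self.key = key
        self.location_text = location_text
        self.qualifiers: dict[str, list[str]] = {}

    def get(self, name: str) -> Optional[str]:
        vals = self.qualifiers.get(name)
        return vals[0] if vals else None

    def has(self, name: str) -> bool:
        return name in self.qualifiers


def _read_entries(stream: IO[str]) -> Iterator[list[str]]:
    """Yield one flat-file entry (list of lines) per LOCUS...// block."""
    lines: list[str] = []
    in_entry = False
    locus = None
    for raw in stream:
        line = raw.rstrip("\n").rstrip("\r")
        if not in_entry:
            if line.startswith("LOCUS"):
                in_entry = True
                locus = line.split()[1] if len(line.split()) > 1 else "?"
                lines = [line]
            continue
        if line.startswith("//"):
            lines.append(line)
            yield lines
            in_entry = False
            lines = []
            continue
        lines.append(line)
    if in_entry:
        raise GenBankParseError(f"truncated entry (no '//' terminator): {locus}")


def _parse_features(lines: list[str], start: int) -> tuple[list[_Feature], int]:
    feats: list[_Feature] = []
    i = start
    cur: Optional[_Feature] = None
    cur_qual: Optional[str] = None
    while i < len(lines):
        line = lines[i]
        if line[:1] not in (" ", ""):  # next top-level keyword (ORIGIN, CONTIG...)
            break
        stripped = line.strip()
        if not stripped:
            i += 1
            continue
        indent = len(line) - len(line.lstrip())
        if indent == 5:  # new feature key
            parts = stripped.split(None, 1)
            cur = _Feature(parts[0], parts[1] if len(parts) > 1 else "")
            cur_qual = None
            feats.append(cur)
        elif cur is not None:
            if stripped.startswith("/"):
                m = re.match(r"^/([\w'\-]+)(?:=(.*))?$", stripped, re.S)
                if m:
                    name, value = m.group(1), m.group(2)
                    if value is None:
                        value = ""
                    cur.qualifiers.setdefault(name, []).append(value)
                    cur_qual = name
                else:
                    cur_qual = None
            elif cur_qual is not None:
                vals = cur.qualifiers[cur_qual]
                # /translation wraps without spaces; free text wraps with one
                joiner = "" if cur_qual == "translation" else " "
                vals[-1] = vals[-1] + joiner + stripped
            else:
                cur.location_text += stripped  # continued location line
        i += 1
    return feats, i


def _unquote(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    value = value.strip()
    if value.startswith('"') and value.endswith('"') and len(value) >= 2:
        value = value[1:-1]
    return value


def _parse_origin(lines: list[str], start: int) -> str:
    seq_parts = []
    for line in lines[start:]:
        if line.startswith("//"):
            break
        if line[:1] not in (" ", ""):
            break
        seq_parts.append(re.sub(r"[\d\s]", "", line))
    return "".join(seq_parts).upper()


def parse_genbank(stream: IO[str], report: Optional[IngestReport] = None) -> Iterator[CDSRecord]:
    """Yield one :class:`CDSRecord` per translated, non-pseudo CDS feature.

    Source-feature annotation (organism, taxon id, entry length and date)
    is attached to every CDS of the containing entry.  Entries without an
    ORIGIN sequence are skipped with a warning; a file ending inside an
    entry raises :class:`GenBankParseError` naming the locus.
    """
    if report is None:
        report = IngestReport()
    for lines in _read_entries(stream):
        report.entries_read += 1
        locus_line = lines[0]
        locus_name = locus_line.split()[1] if len(locus_line.split()) > 1 else "?"
        entry_date = _parse_locus_date(locus_line)
        source_accession = locus_name
        feat_start = origin_start = None
        for i, line in enumerate(lines):
            if line.startswith("VERSION"):
                parts = line.split()
                if len(parts) > 1:
                    source_accession = parts[1]
            elif line.startswith("ACCESSION") and source_accession == locus_name:
                parts = line.split()
                if len(parts) > 1:
                    source_accession = parts[1]
            elif line.startswith("FEATURES"):
                feat_start = i + 1
            elif line.startswith("ORIGIN"):
                origin_start = i + 1
                break
        if feat_start is None:
            logger.warning("entry %s has no FEATURES table; skipped", locus_name)
            continue
        if origin_start is None:
            logger.warning("entry %s has no ORIGIN sequence; skipped", locus_name)
            report.entries_without_sequence += 1
            continue
        features, _ = _parse_features(lines, feat_start)
        origin = _parse_origin(lines, origin_start)
        if not origin:
            logger.warning("entry %s has an empty ORIGIN sequence; skipped", locus_name)
            report.entries_without_sequence += 1
            continue

        organism = ""
        taxon_id: Optional[int] = None
        for feat in features:
            if feat.key == "source":
                organism = _unquote(feat.get("organism")) or ""
                for xref in feat.qualifiers.get("db_xref", []):
                    xref = _unquote(xref) or ""
                    if xref.startswith("taxon:"):
                        try:
                            taxon_id = int(xref.split(":", 1)[1])
                        except ValueError:
                            pass
                break

        for feat in features:
            if feat.key != "CDS":
                continue
            if feat.has("pseudo") or feat.has("pseudogene"):
                report.pseudo_skipped += 1
                continue
            translation = _unquote(feat.get("translation"))
            if not translation:
                report.no_translation_skipped += 1
                continue
            loc = parse_location(feat.location_text)
            p5, p3 = partial_flags(loc)
            gi = None
            for xref in feat.qualifiers.get("db_xref", []):
                xref = _unquote(xref) or ""
                if xref.startswith("GI:"):
                    try:
                        gi = int(xref.split(":", 1)[1])
                    except ValueError:
                        pass
            record = CDSRecord(
                protein_accession=_unquote(feat.get("protein_id")) or "",
                source_accession=source_accession,
                taxon_id=taxon_id,
                organism=organism,
                dna_seq=splice(origin, loc),
                aa_seq="".join(translation.split()),
                location=loc,
                gi=gi,
                gene=_unquote(feat.get("gene")),
                product=_unquote(feat.get("product")),
                locus_tag=_unquote(feat.get("locus_tag")),
                note=_unquote(feat.get("note")),
                codon_start=int(_unquote(feat.get("codon_start")) or 1),
                transl_table=int(_unquote(feat.get("transl_table")) or 1),
                partial5=p5,
                partial3=p3,
                source_length=len(origin),
                entry_date=entry_date,
            )
            report.cds_kept += 1
            yield record
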