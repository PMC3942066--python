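"""Turn user selections (identifier lists or FASTA) into stored CDS records.

Selection input is either one identifier per line (accession, versioned
accession, or GI) or FASTA.  FASTA title lines in NCBI style contribute
identifiers to try first; when identifiers fail, the sequence itself is
hashed and looked up (case-insensitively) in the protein and then the
DNA index, optionally restricted to the species named in square brackets
on the title line.  A sequence that matches nothing is passed through
with only its label, sequence and any bracket-derived taxonomy attached.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from cdskit.genbank import CDSRecord, sequence_md5
from cdskit.store import CDSStore
from cdskit.taxonomy import TaxonomyDB

logger = logging.getLogger(__name__)

_DNA_CHARS = frozenset("ACGTNU")


@dataclass
class SelectorItem:
    """One requested sequence: identifiers and/or a literal sequence."""

    raw_label: str
    identifiers: list[str] = field(default_factory=list)
    sequence: Optional[str] = None
    seq_kind: str = "unknown"  # dna | protein | unknown
    species_hint: Optional[str] = None
    input_ordinal: int = 0


@dataclass
class Resolution:
    item: SelectorItem
    matched: list[CDSRecord] = field(default_factory=list)
    passthrough: Optional[CDSRecord] = None

    @property
    def resolved(self) -> bool:
        return bool(self.matched) or self.passthrough is not None


def guess_seq_kind(seq: str) -> str:
    """DNA when at least 90% of characters are in {A,C,G,T,N,U}."""
    if not seq:
        return "unknown"
    up = seq.upper()
    frac = sum(c in _DNA_CHARS for c in up) / len(up)
    return "dna" if frac >= 0.90 else "protein"


_BRACKET_RE = re.compile(r"\[([^\[\]]+)\]\s*$")
_ACC_RE = re.compile(r"^[A-Z]{1,4}_?\d+(\.\d+)?$")


def _parse_header(header: str) -> tuple[list[str], Optional[str]]:
    """Identifiers (accession before GI) and species hint from a title line."""
    header = header.strip()
    species_hint = None
    m = _BRACKET_RE.search(header)
    if m:
        species_hint = m.group(1).strip()
    identifiers: list[str] = []
    first = header.split()[0] if header.split() else ""
    if "|" in first:
        # NCBI pipe style: gi|450145|ref|NP_000509.1|
        fields = first.split("|")
        gi_tokens = [
            fields[i + 1]
            for i, f in enumerate(fields[:-1])
            if f == "gi" and fields[i + 1].isdigit()
        ]
        acc_tokens = [f for f in fields if _ACC_RE.match(f) and not f.isdigit()]
        identifiers = acc_tokens + gi_tokens
    elif first and (_ACC_RE.match(first) or first.isdigit()):
        identifiers = [first]
    return identifiers, species_hint


def parse_selection(text: str) -> list[SelectorItem]:
    """Parse identifier-list or FASTA selection text into SelectorItems.

    Text whose first non-blank character is ``>`` is FASTA (wrapped lines
    and CRLF tolerated); anything else is one identifier per line.
    """
    stripped = text.lstrip()
    if not stripped:
        raise ValueError("empty selection")
    if stripped.startswith(">"):
        return _parse_fasta(text)
    items = []
    ordinal = 0
    for line in text.splitlines():
        token = line.strip()
        if not token:
            continue
        ordinal += 1
        identifiers, hint = _parse_header(token)
        items.append(
            SelectorItem(
                raw_label=token,
                identifiers=identifiers or [token],
                species_hint=hint,
                input_ordinal=ordinal,
            )
        )
    return items


def _parse_fasta(text: str) -> list[SelectorItem]:
    items: list[SelectorItem] = []
    header: Optional[str] = None
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(seq_parts)
        if not seq:
            raise ValueError(f"FASTA record with empty sequence: >{header}")
        identifiers, hint = _parse_header(header)
        items.append(
            SelectorItem(
                raw_label=header,
                identifiers=identifiers,
                sequence=seq.upper(),
                seq_kind=guess_seq_kind(seq),
                species_hint=hint,
                input_ordinal=len(items) + 1,
            )
        )

    for line in text.splitlines():
        line = line.rstrip("\r")
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            seq_parts = []
        elif line.strip():
            seq_parts.append("".join(line.split()))
    flush()
    return items


def resolve(
    item: SelectorItem, store: CDSStore, taxonomy: Optional[TaxonomyDB] = None
) -> Resolution:
    """Resolve one SelectorItem against the store.

    Identifiers are tried in order; on failure a present sequence is
    hashed and looked up in the protein index, then the DNA index,
    restricted to the bracket species when that name resolves in the
    taxonomy.  A sequence with no match becomes a passthrough record; an
    identifier-only item with no match is reported unresolved.  Failures
    are data, not exceptions.
    """
    for ident in item.identifiers:
        rec = store.get_by_id(ident)
        if rec is not None:
            return Resolution(item=item, matched=[rec])

    if item.sequence is None:
        return Resolution(item=item)

    taxon_restrict: Optional[int] = None
    if item.species_hint and taxonomy is not None:
        node = taxonomy.find_by_name(item.species_hint)
        if node is not None:
            taxon_restrict = node.tax_id
        else:
            logger.warning(
                "species hint %r not found in taxonomy; restriction disabled",
                item.species_hint,
            )

    md5 = sequence_md5(item.sequence)
    for kind in ("protein", "dna"):
        matches = store.get_by_hash(md5, kind, taxon_restrict)
        if matches:
            return Resolution(item=item, matched=matches)

    # passthrough: keep the sequence, annotation-free except hint taxonomy
    is_dna = item.seq_kind == "dna"
    passthrough = CDSRecord(
        protein_accession="",
        source_accession="",
        taxon_id=taxon_restrict,
        organism=(
            taxonomy.node(taxon_restrict).scientific_name
            if taxonomy is not None and taxon_restrict is not None
            else (item.species_hint or "")
        ),
        dna_seq=item.sequence if is_dna else "",
        aa_seq="" if is_dna else item.sequence,
        passthrough=True,
    )
    return Resolution(item=item, passthrough=passthrough)
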