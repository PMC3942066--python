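"""Label templating, sanitization and sequence output.

Labels and comments are rendered from per-record annotation dictionaries
with printf-style ``%(keyword)s`` templates — the dictionary-formatting
idiom familiar from Python — restricted to the three conversions the
label language needs: ``%(key)s``, ``%(key).Ns`` (truncate to N
characters) and ``%(key)M.Nf`` (fixed-point float in an M-wide field).
Unknown keys render as empty strings with a warning so one odd record
can never abort a batch.

Output modes: amino acid or DNA FASTA, third-codon-position R/Y wobble
recoding (plus whole-sequence R/Y recoding as an extension), or ``none``
— a two-column labeled property file for tree relabeling/annotation
tools such as iTOL.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date
from typing import IO, Optional, Sequence

from cdskit.genbank import CDSRecord
from cdskit.taxonomy import TaxonomyDB

logger = logging.getLogger(__name__)

PRESETS: dict[str, tuple[str, str]] = {
    # label template, comment template
    "common_name": (">%(ComName)s", "[%(SciName)s]"),
    "identifiers": (">%(acv)s", "gi|%(gi)s [%(SciName)s]"),
    "species": (">%(SciName)s", ""),
    "gene": (">%(gene)s", "[%(SciName)s]"),
    "original": (">%(origLabel)s", ""),
}

SEQUENCE_MODES = ("aa", "dna", "wobble_ry", "ry", "none")


@dataclass
class LabelSpec:
    label_template: str = ">%(ComName)s"
    comment_template: str = "[%(SciName)s]"
    max_length: Optional[int] = None
    charset_policy: str = "permissive"  # or "strict"
    preset: Optional[str] = None

    def __post_init__(self) -> None:
        if self.preset is not None:
            try:
                self.label_template, self.comment_template = PRESETS[self.preset]
            except KeyError:
                raise ValueError(f"unknown label preset {self.preset!r}") from None
        if self.charset_policy not in ("strict", "permissive"):
            raise ValueError(f"unknown charset policy {self.charset_policy!r}")


def build_annotation(
    record: CDSRecord,
    taxonomy: Optional[TaxonomyDB],
    ordinal: int,
    today: Optional[date] = None,
    orig_label: str = "",
) -> dict[str, object]:
    """Assemble the keyword→value dictionary behind label templates.

    Guaranteed keys: ``acv``, ``gi``, ``taxID``, ``SciName``, ``ComName``
    (falling back to the scientific name when no common name exists),
    ``gene``, ``product``, ``genus``, ``species`` (the epithet, i.e. the
    binomial minus the genus), every named taxonomic rank on the lineage
    (``order``, ``family``, ...), ``sqNr`` (1-based output ordinal),
    ``today`` (ISO date, injectable for reproducible runs), ``pcGC``,
    ``length`` and ``origLabel``.  Absent values are empty strings.
    """
    ann: dict[str, object] = {
        "acv": record.protein_accession or "",
        "gi": record.gi if record.gi is not None else "",
        "taxID": record.taxon_id if record.taxon_id is not None else "",
        "SciName": record.organism or "",
        "ComName": record.organism or "",
        "gene": record.gene or "",
        "product": record.product or "",
        "locus_tag": record.locus_tag or "",
        "note": record.note or "",
        "sqNr": ordinal,
        "today": (today or date.today()).isoformat(),
        "pcGC": record.pcGC,
        "length": record.cds_length if record.dna_seq else len(record.aa_seq),
        "origLabel": orig_label,
        "srcAcc": record.source_accession or "",
        "genus": "",
        "species": "",
    }
    sci = record.organism or ""
    if taxonomy is not None and record.taxon_id is not None and record.taxon_id in taxonomy:
        lineage = taxonomy.lineage(record.taxon_id)
        node = lineage[-1]
        sci = node.scientific_name or sci
        ann["SciName"] = sci
        ann["ComName"] = node.common_name or sci
        for anc in lineage:
            if anc.rank and anc.rank != "no rank" and anc.rank != "species":
                ann[anc.rank] = anc.scientific_name
        genus_node = next((n for n in lineage if n.rank == "genus"), None)
        if genus_node is not None:
            ann["genus"] = genus_node.scientific_name
    if not ann["genus"] and sci:
        ann["genus"] = sci.split()[0]
    genus = str(ann["genus"])
    if sci:
        # species epithet: the binomial with its genus prefix removed
        if genus and sci.startswith(genus + " "):
            ann["species"] = sci[len(genus) + 1 :]
        elif " " in sci:
            ann["species"] = sci.split(None, 1)[1]
        else:
            ann["species"] = sci
    return ann


class TemplateError(ValueError):
    pass


_SPEC_RE = re.compile(r"%\(([^()]*)\)(-?\d+)?(?:\.(\d+))?([a-zA-Z%])")


def render(template: str, annotation: dict[str, object]) -> str:
    """printf-style substitution restricted to s and f conversions.

    ``%(key)s`` inserts the value; ``%(key).Ns`` truncates to N
    characters; ``%(key)M.Nf`` renders a float, N digits after the
    point, right-aligned in an M-wide field.  Unknown keys render empty
    with a warning; a malformed conversion raises
    :class:`TemplateError` naming the position.
    """
    out: list[str] = []
    pos = 0
    while True:
        idx = template.find("%", pos)
        if idx < 0:
            out.append(template[pos:])
            break
        out.append(template[pos:idx])
        if template.startswith("%%", idx):
            out.append("%")
            pos = idx + 2
            continue
        m = _SPEC_RE.match(template, idx)
        if not m:
            raise TemplateError(
                f"malformed conversion at position {idx} in {template!r}"
            )
        key, width_s, prec_s, conv = m.groups()
        if conv not in ("s", "f"):
            raise TemplateError(
                f"unsupported conversion %{conv!r} at position {idx} in {template!r}"
            )
        if key in annotation:
            value = annotation[key]
        else:
            logger.warning("unknown label keyword %r; rendered empty", key)
            value = ""
        if conv == "s":
            text = "" if value is None else str(value)
            if prec_s is not None:
                text = text[: int(prec_s)]
            if width_s is not None:
                width = int(width_s)
                text = text.ljust(-width) if width < 0 else text.rjust(width)
        else:
            try:
                number = float(value) if value != "" else 0.0
            except (TypeError, ValueError):
                logger.warning("keyword %r is not numeric; rendered as 0", key)
                number = 0.0
            prec = int(prec_s) if prec_s is not None else 6
            text = f"{number:.{prec}f}"
            if width_s is not None:
                width = int(width_s)
                text = text.ljust(-width) if width < 0 else text.rjust(width)
        out.append(text)
        pos = m.end()
    return "".join(out)


_STRICT_RE = re.compile(r"[^A-Za-z0-9_.\-]")


def finalize_labels(labels: Sequence[str], spec: LabelSpec) -> list[str]:
    """Sanitize, truncate and uniquify labels, preserving order.

    Strict charset maps anything outside ``[A-Za-z0-9_.-]`` to ``_``;
    truncation to ``max_length`` happens before uniquification, so a
    ``_k`` suffix (k = 2, 3, ...) may exceed the limit by its own width.
    The first occurrence of a duplicate keeps its plain label.
    """
    out: list[str] = []
    seen: dict[str, int] = {}
    for label in labels:
        lead = ""
        if label.startswith(">"):
            lead, label = ">", label[1:]
        if spec.charset_policy == "strict":
            label = _STRICT_RE.sub("_", label)
        if spec.max_length is not None:
            label = label[: spec.max_length]
        base = label
        count = seen.get(base, 0)
        if count:
            label = f"{base}_{count + 1}"
            while label in seen:  # collision with a literal "x_2" input
                count += 1
                label = f"{base}_{count + 1}"
        seen[base] = count + 1
        seen.setdefault(label, 1)
        out.append(lead + label)
    return out


_WOBBLE = {"A": "R", "G": "R", "C": "Y", "T": "Y", "R": "R", "Y": "Y"}


def wobble_ry(dna: str) -> str:
    """Recode every third codon position as R (purine) / Y (pyrimidine) / N."""
    chars = list(dna)
    for i in range(2, len(chars), 3):
        chars[i] = _WOBBLE.get(chars[i].upper(), "N")
    return "".join(chars)


def ry_recode(dna: str) -> str:
    """Whole-sequence purine/pyrimidine recoding (extension mode)."""
    return "".join(_WOBBLE.get(c.upper(), "N") for c in dna)


def encode_sequence(record: CDSRecord, mode: str) -> Optional[str]:
    """Pick the output sequence for a record, or ``None``.

    ``aa`` → the protein; ``dna`` → the spliced CDS; ``wobble_ry`` →
    the CDS with third codon positions R/Y-recoded; ``ry`` → the fully
    R/Y-recoded CDS; ``none`` → no sequence (property-file output).  DNA
    modes on a record without a CDS (protein passthrough) return
    ``None`` so the caller can skip it with a warning.
    """
    if mode == "none":
        return None
    if mode == "aa":
        return record.aa_seq or None
    if mode in ("dna", "wobble_ry", "ry"):
        if not record.dna_seq:
            return None
        if mode == "dna":
            return record.dna_seq
        return wobble_ry(record.dna_seq) if mode == "wobble_ry" else ry_recode(record.dna_seq)
    raise ValueError(f"unknown sequence mode {mode!r}")


def write_output(
    records: Sequence[CDSRecord],
    labels: Sequence[str],
    comments: Sequence[str],
    mode: str,
    stream: IO[str],
    wrap: int = 60,
) -> int:
    """Write FASTA (sequence modes) or a labeled property file (``none``).

    FASTA headers are ``label comment`` (single separating space, comment
    omitted when empty) with the sequence wrapped at ``wrap`` columns; a
    leading ``>`` is prepended when the label lacks one.  Property files
    get one ``label<TAB>comment`` line per record (no ``>``).  Records a
    DNA mode cannot serve are skipped with a warning.  Returns the
    number of records written.
    """
    if not (len(records) == len(labels) == len(comments)):
        raise ValueError("records, labels and comments must have equal length")
    written = 0
    for record, label, comment in zip(records, labels, comments):
        if mode == "none":
            stream.write(f"{label.lstrip('>')}\t{comment}\n")
            written += 1
            continue
        seq = encode_sequence(record, mode)
        if seq is None:
            logger.warning(
                "record %r has no sequence for mode %s; skipped",
                label,
                mode,
            )
            continue
        header = label if label.startswith(">") else ">" + label
        if comment:
            header = f"{header} {comment}"
        stream.write(header + "\n")
        for i in range(0, len(seq), wrap):
            stream.write(seq[i : i + wrap] + "\n")
        written += 1
    return written
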