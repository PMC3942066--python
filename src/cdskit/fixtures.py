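"""Synthetic GenBank flat files and toy taxonomy dumps, with ground truth.

Every other module is testable offline against data this generator
emits.  The generator writes the expected parse result for each CDS
alongside the flat file (generator-as-oracle), so ingest tests assert
field-by-field against a truth table that was *constructed*, never
re-derived from the parser under test.

Sequences are random with controlled composition, not evolved: protein
sequences are drawn uniformly from the 20 standard amino acids and
back-translated through the standard codon table, so ``/translation``
genuinely corresponds to the spliced CDS and a complete CDS satisfies
``len(dna) == 3 * (len(aa) + 1)`` by construction.  Same seed, same
bytes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from cdskit.genbank import reverse_complement

# standard codon table, inverted: aa -> codons (stop handled separately)
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_AA_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_AA_TABLE):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _CODONS.setdefault(_aa, []).append(_codon)
STOP_CODONS = _CODONS.pop("*")


@dataclass
class ToyTaxon:
    tax_id: int
    parent_id: int
    rank: str
    scientific_name: str
    common_name: Optional[str] = None


#: Hand-built primate lineage used by golden tests: root → Primates →
#: Hominidae → Homo → Homo sapiens (9606, common name "human"), plus a
#: second hominid, a rodent and a virus for cross-taxon scenarios.
BASE_TAXA: list[ToyTaxon] = [
    ToyTaxon(1, 1, "no rank", "root"),
    ToyTaxon(2759, 1, "superkingdom", "Eukaryota"),
    ToyTaxon(9443, 2759, "order", "Primates", "primates"),
    ToyTaxon(9604, 9443, "family", "Hominidae", "great apes"),
    ToyTaxon(9605, 9604, "genus", "Homo"),
    ToyTaxon(9606, 9605, "species", "Homo sapiens", "human"),
    ToyTaxon(9592, 9604, "genus", "Gorilla"),
    ToyTaxon(9593, 9592, "species", "Gorilla gorilla", "western gorilla"),
    ToyTaxon(9989, 2759, "order", "Rodentia", "rodents"),
    ToyTaxon(10088, 9989, "genus", "Mus"),
    ToyTaxon(10090, 10088, "species", "Mus musculus", "house mouse"),
    ToyTaxon(10239, 1, "superkingdom", "Viruses"),
    ToyTaxon(12059, 10239, "family", "Picornaviridae"),
    ToyTaxon(12110, 12059, "species", "Foot-and-mouth disease virus"),
]


@dataclass
class FixtureSpec:
    """Knobs of the synthetic data; defaults cover the full case grid."""

    seed: int = 0
    n_entries: int = 30
    cds_per_entry: tuple[int, int] = (1, 4)
    frac_partial5: float = 0.15
    frac_partial3: float = 0.15
    frac_pseudo: float = 0.10
    frac_no_translation: float = 0.05
    frac_ambiguous_dna: float = 0.10
    frac_ambiguous_aa: float = 0.05
    frac_minus_strand: float = 0.40
    frac_spliced: float = 0.40
    aa_length: tuple[int, int] = (10, 60)
    n_extra_taxa: int = 10
    refseq_fraction: float = 0.3


@dataclass
class GroundTruth:
    """Expected parse outcome for one emitted CDS feature."""

    protein_accession: str
    gi: Optional[int]
    source_accession: str
    taxon_id: int
    organism: str
    dna_seq: str
    aa_seq: str
    partial5: bool
    partial3: bool
    codon_start: int
    transl_table: int
    gene: Optional[str]
    product: Optional[str]
    source_length: int
    location_text: str
    skip: Optional[str] = None  # None | "pseudo" | "no_translation"


def make_taxdump(spec: FixtureSpec) -> tuple[str, str, list[ToyTaxon]]:
    """nodes.dmp / names.dmp text for the base lineage plus random genera."""
    rng = random.Random(spec.seed)
    taxa = list(BASE_TAXA)
    next_id = 500000
    genera = [t for t in BASE_TAXA if t.rank == "genus"]
    for i in range(spec.n_extra_taxa):
        parent = rng.choice(genera)
        next_id += rng.randint(1, 9)
        taxa.append(
            ToyTaxon(
                next_id,
                parent.tax_id,
                "species",
                f"{parent.scientific_name} synthetica{i}",
                f"toy species {i}" if rng.random() < 0.5 else None,
            )
        )
    nodes_lines = [
        f"{t.tax_id}\t|\t{t.parent_id}\t|\t{t.rank}\t|" for t in taxa
    ]
    names_lines = []
    for t in taxa:
        names_lines.append(
            f"{t.tax_id}\t|\t{t.scientific_name}\t|\t\t|\tscientific name\t|"
        )
        if t.common_name:
            names_lines.append(
                f"{t.tax_id}\t|\t{t.common_name}\t|\t\t|\tgenbank common name\t|"
            )
        # a synonym line that loaders must ignore
        if t.tax_id == 9606:
            names_lines.append(f"{t.tax_id}\t|\tman\t|\t\t|\tsynonym\t|")
    return "\n".join(nodes_lines) + "\n", "\n".join(names_lines) + "\n", taxa


def random_protein(rng: random.Random, length: int) -> str:
    return "M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length - 1))


def back_translate(rng: random.Random, aa: str) -> str:
    return "".join(rng.choice(_CODONS[c]) for c in aa)


def _wrap_translation(aa: str) -> list[str]:
    lines = []
    text = f'/translation="{aa}"'
    width = 58
    for i in range(0, len(text), width):
        prefix = "                     "
        lines.append(prefix + text[i : i + width])
    return lines


def _origin_block(seq: str) -> list[str]:
    lines = ["ORIGIN"]
    low = seq.lower()
    for i in range(0, len(low), 60):
        chunk = low[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    return lines


def make_genbank(spec: FixtureSpec) -> tuple[str, list[GroundTruth]]:
    """Emit flat-file text plus the per-CDS expected-parse truth table."""
    rng = random.Random(spec.seed + 1)
    _, _, taxa = make_taxdump(spec)
    species = [t for t in taxa if t.rank == "species"]
    truths: list[GroundTruth] = []
    entries: list[str] = []
    gi_counter = 700000
    acc_counter = 0

    for entry_idx in range(spec.n_entries):
        taxon = rng.choice(species)
        source_acc = f"CU{entry_idx + 1:06d}.1"
        locus = f"CU{entry_idx + 1:06d}"
        n_cds = rng.randint(*spec.cds_per_entry)

        cds_specs = []
        origin_parts: list[str] = []
        pos = 1

        def emit_flank() -> None:
            nonlocal pos
            flank = "".join(rng.choice("acgt") for _ in range(rng.randint(10, 40))).upper()
            origin_parts.append(flank)
            pos += len(flank)

        emit_flank()
        for _ in range(n_cds):
            acc_counter += 1
            gi_counter += rng.randint(1, 5)
            refseq = rng.random() < spec.refseq_fraction
            protein_acc = (
                f"NP_{acc_counter:06d}.1" if refseq else f"AAB{acc_counter:05d}.1"
            )
            aa_len = rng.randint(*spec.aa_length)
            aa = random_protein(rng, aa_len)
            partial5 = rng.random() < spec.frac_partial5
            partial3 = rng.random() < spec.frac_partial3
            skip: Optional[str] = None
            if rng.random() < spec.frac_pseudo:
                skip = "pseudo"
            elif rng.random() < spec.frac_no_translation:
                skip = "no_translation"

            dna = back_translate(rng, aa)
            codon_start = 1
            if partial5:
                # drop the initial codon and its residue; keep frame honest
                aa = aa[1:]
                dna = dna[3:]
            if not partial3:
                dna += rng.choice(STOP_CODONS)
            if rng.random() < spec.frac_ambiguous_dna:
                k = rng.randrange(len(dna))
                dna = dna[:k] + "N" + dna[k + 1 :]
            if rng.random() < spec.frac_ambiguous_aa:
                k = rng.randrange(1, len(aa))
                aa = aa[:k] + "X" + aa[k + 1 :]

            minus = rng.random() < spec.frac_minus_strand
            spliced = rng.random() < spec.frac_spliced and len(dna) >= 12

            genomic = reverse_complement(dna) if minus else dna
            if spliced:
                cut = 3 * rng.randint(1, len(genomic) // 3 - 1)
                seg_a, seg_b = genomic[:cut], genomic[cut:]
                start_a = pos
                origin_parts.append(seg_a)
                pos += len(seg_a)
                end_a = pos - 1
                intron = "".join(
                    rng.choice("acgt") for _ in range(rng.randint(8, 30))
                ).upper()
                origin_parts.append(intron)
                pos += len(intron)
                start_b = pos
                origin_parts.append(seg_b)
                pos += len(seg_b)
                end_b = pos - 1
                left_mark = "<" if (partial3 if minus else partial5) else ""
                right_mark = ">" if (partial5 if minus else partial3) else ""
                inner = (
                    f"join({left_mark}{start_a}..{end_a},"
                    f"{start_b}..{right_mark}{end_b})"
                )
                loc_text = f"complement({inner})" if minus else inner
            else:
                start = pos
                origin_parts.append(genomic)
                pos += len(genomic)
                end = pos - 1
                left_mark = "<" if (partial3 if minus else partial5) else ""
                right_mark = ">" if (partial5 if minus else partial3) else ""
                inner = f"{left_mark}{start}..{right_mark}{end}"
                loc_text = f"complement({inner})" if minus else inner
            emit_flank()

            gene = f"gene{acc_counter}" if rng.random() < 0.8 else None
            product = f"hypothetical protein {acc_counter}"
            cds_specs.append(
                dict(
                    protein_acc=protein_acc,
                    gi=gi_counter,
                    aa=aa,
                    dna=dna,
                    loc_text=loc_text,
                    partial5=partial5,
                    partial3=partial3,
                    codon_start=codon_start,
                    gene=gene,
                    product=product,
                    skip=skip,
                )
            )

        origin = "".join(origin_parts)
        lines = [
            f"LOCUS       {locus:<16}{len(origin):>12} bp    DNA     linear   "
            f"SYN 10-MAY-2013",
            f"DEFINITION  synthetic test entry {entry_idx + 1}.",
            f"ACCESSION   {locus}",
            f"VERSION     {source_acc}",
            "FEATURES             Location/Qualifiers",
            f"     source          1..{len(origin)}",
            f'                     /organism="{taxon.scientific_name}"',
            f'                     /db_xref="taxon:{taxon.tax_id}"',
        ]
        for cs in cds_specs:
            lines.append(f"     CDS             {cs['loc_text']}")
            if cs["gene"]:
                lines.append(f'                     /gene="{cs["gene"]}"')
            lines.append(f'                     /product="{cs["product"]}"')
            if cs["skip"] == "pseudo":
                lines.append("                     /pseudo")
            else:
                lines.append(f"                     /codon_start={cs['codon_start']}")
                lines.append("                     /transl_table=1")
                lines.append(f'                     /protein_id="{cs["protein_acc"]}"')
                lines.append(f'                     /db_xref="GI:{cs["gi"]}"')
                if cs["skip"] != "no_translation":
                    lines.extend(_wrap_translation(cs["aa"]))
            truths.append(
                GroundTruth(
                    protein_accession=cs["protein_acc"],
                    gi=cs["gi"],
                    source_accession=source_acc,
                    taxon_id=taxon.tax_id,
                    organism=taxon.scientific_name,
                    dna_seq=cs["dna"],
                    aa_seq=cs["aa"],
                    partial5=cs["partial5"],
                    partial3=cs["partial3"],
                    codon_start=cs["codon_start"],
                    transl_table=1,
                    gene=cs["gene"],
                    product=cs["product"],
                    source_length=len(origin),
                    location_text=cs["loc_text"],
                    skip=cs["skip"],
                )
            )
        lines.extend(_origin_block(origin))
        lines.append("//")
        entries.append("\n".join(lines))

    return "\n".join(entries) + "\n", truths
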