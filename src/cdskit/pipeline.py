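"""The selection engine: expansion, redundancy clustering, quality control
and cluster-representative choice.

The pipeline mirrors how an expert curates a sequence set by hand:

1. *expand* a selection to synonymous CDS and/or identical proteins in
   other taxa, via the MD5 indices;
2. *cluster* redundant entries under one of the redundancy keys
   (accession, protein or DNA sequence identity — optionally per taxon —
   or a taxonomic rank);
3. *flag* imperfect members (incomplete ends, ambiguous residues,
   length out of range);
4. pick each cluster's *representative* by, in order: species importance
   (CDS count as a proxy for how well-studied the species is), RefSeq
   membership, how often the protein sequence occurs in the store, CDS
   length, source entry length, and finally input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from cdskit.genbank import CDSRecord, STANDARD_AA, STANDARD_NT
from cdskit.resolver import Resolution, SelectorItem, resolve
from cdskit.store import CDSStore
from cdskit.taxonomy import TaxonomyDB

logger = logging.getLogger(__name__)

EXPANSION_MODES = ("none", "full", "cds_within_taxon")
REDUNDANCY_KEYS = (
    "accession",
    "protein_seq",
    "dna_seq",
    "protein_seq_by_taxon",
    "dna_seq_by_taxon",
)  # plus "tax_rank:<rank>"


@dataclass
class PipelineConfig:
    """Complete user-controllable selection state.

    Defaults are the common path: accession-keyed redundancy, the four
    completeness/ambiguity flags enabled, no length window, best-effort
    representatives for clusters where nothing passes.
    """

    expansion: str = "none"
    redundancy_key: str = "accession"
    require_n_complete: bool = True
    require_c_complete: bool = True
    require_dna_clean: bool = True
    require_aa_clean: bool = True
    length_range: Optional[tuple[int, int]] = None
    empty_cluster_policy: str = "best_effort"  # or "drop"
    output_kind: str = "dna"  # sequence kind quality/length checks apply to

    def __post_init__(self) -> None:
        if self.expansion not in EXPANSION_MODES:
            raise ValueError(f"unknown expansion mode {self.expansion!r}")
        key = self.redundancy_key
        if key not in REDUNDANCY_KEYS and not key.startswith("tax_rank:"):
            raise ValueError(f"unknown redundancy key {key!r}")
        if self.empty_cluster_policy not in ("best_effort", "drop"):
            raise ValueError(
                f"unknown empty_cluster_policy {self.empty_cluster_policy!r}"
            )


@dataclass
class QualityFlags:
    n_incomplete: bool = False
    c_incomplete: bool = False
    dna_ambiguous: bool = False
    aa_ambiguous: bool = False
    length_out_of_range: bool = False
    passes: bool = True


@dataclass
class Cluster:
    key: object
    members: list[tuple[CDSRecord, QualityFlags, int]] = field(default_factory=list)
    representative: Optional[CDSRecord] = None
    representative_ordinal: Optional[int] = None


@dataclass
class RunReport:
    items: int = 0
    resolved: int = 0
    unresolved: int = 0
    unresolved_labels: list[str] = field(default_factory=list)
    passthrough: int = 0
    expanded: int = 0
    clusters: int = 0
    clusters_dropped: int = 0
    output_records: int = 0
    output_ordinals: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def expand(
    records: list[tuple[CDSRecord, int]], mode: str, store: CDSStore
) -> list[tuple[CDSRecord, int]]:
    """Expand records to hash-sharing store entries.

    ``full`` adds every record sharing the protein MD5 across all taxa
    (full taxonomic coverage and all synonymous CDS); ``cds_within_taxon``
    adds synonymous CDS variants without expanding taxonomic coverage.
    Records are (record, input_ordinal) pairs; duplicates arising from
    overlapping expansions are kept once, at first appearance.
    """
    if mode == "none":
        return list(records)
    out: list[tuple[CDSRecord, int]] = []
    seen: set[str] = set()

    def push(rec: CDSRecord, ordinal: int) -> None:
        key = rec.protein_accession or f"@{id(rec)}"
        if key not in seen:
            seen.add(key)
            out.append((rec, ordinal))

    for rec, ordinal in records:
        push(rec, ordinal)
        if not rec.prot_md5 or rec.passthrough:
            continue
        taxon = rec.taxon_id if mode == "cds_within_taxon" else None
        for hit in store.get_by_hash(rec.prot_md5, "protein", taxon):
            push(hit, ordinal)
    return out


def quality_flags(record: CDSRecord, config: PipelineConfig) -> QualityFlags:
    """Evaluate the five quality flags for one record.

    Completeness comes from the stored partial-end flags (false for
    passthrough records, whose provenance is unknown); ambiguity is any
    character outside A/C/G/T for DNA or outside the 20 standard amino
    acids for protein; the length window applies to the output sequence
    kind.
    """
    out_seq = record.dna_seq if config.output_kind == "dna" else record.aa_seq
    length_bad = False
    if config.length_range is not None:
        lo, hi = config.length_range
        length_bad = not (lo <= len(out_seq) <= hi)
    flags = QualityFlags(
        n_incomplete=record.partial5,
        c_incomplete=record.partial3,
        dna_ambiguous=record.dna_ambiguous,
        aa_ambiguous=record.aa_ambiguous,
        length_out_of_range=length_bad,
    )
    failed = (
        (config.require_n_complete and flags.n_incomplete)
        or (config.require_c_complete and flags.c_incomplete)
        or (config.require_dna_clean and flags.dna_ambiguous)
        or (config.require_aa_clean and flags.aa_ambiguous)
        or (config.length_range is not None and flags.length_out_of_range)
    )
    flags.passes = not failed
    return flags


def cluster_key(
    record: CDSRecord, key_spec: str, taxonomy: Optional[TaxonomyDB]
) -> object:
    if key_spec == "accession":
        return record.protein_accession or f"@{id(record)}"
    if key_spec == "protein_seq":
        return record.prot_md5 or f"@{id(record)}"
    if key_spec == "dna_seq":
        return record.dna_md5 or f"@{id(record)}"
    if key_spec == "protein_seq_by_taxon":
        return (record.prot_md5 or f"@{id(record)}", record.taxon_id)
    if key_spec == "dna_seq_by_taxon":
        return (record.dna_md5 or f"@{id(record)}", record.taxon_id)
    if key_spec.startswith("tax_rank:"):
        rank = key_spec.split(":", 1)[1]
        if (
            taxonomy is not None
            and record.taxon_id is not None
            and record.taxon_id in taxonomy
        ):
            node = taxonomy.ancestor_at_rank(record.taxon_id, rank)
            if node is not None:
                return node.tax_id
        # rank absent (or taxon unknown): the record clusters alone
        return ("_self", record.taxon_id, record.protein_accession or id(record))
    raise ValueError(f"unknown redundancy key {key_spec!r}")


def cluster(
    records: list[tuple[CDSRecord, QualityFlags, int]],
    key_spec: str,
    taxonomy: Optional[TaxonomyDB] = None,
) -> list[Cluster]:
    """Partition flagged records into redundancy clusters.

    Clusters are ordered by first member appearance; member order within
    a cluster follows the (expanded) input.
    """
    by_key: dict[object, Cluster] = {}
    order: list[Cluster] = []
    for rec, flags, ordinal in records:
        key = cluster_key(rec, key_spec, taxonomy)
        cl = by_key.get(key)
        if cl is None:
            cl = Cluster(key=key)
            by_key[key] = cl
            order.append(cl)
        cl.members.append((rec, flags, ordinal))
    return order


def _ambiguity_score(record: CDSRecord, output_kind: str) -> int:
    """Number of non-ambiguous residues in the output sequence kind."""
    if output_kind == "dna":
        return sum(c in STANDARD_NT for c in record.dna_seq)
    return sum(c in STANDARD_AA for c in record.aa_seq)


def selection_key(
    record: CDSRecord,
    ordinal: int,
    store: Optional[CDSStore],
    taxonomy: Optional[TaxonomyDB],
) -> tuple:
    """The lexicographic preference tuple, larger is better.

    Order: species importance, RefSeq membership, protein representation
    count in the store, CDS length, source entry length, then earliest
    input position.  Passthrough records score 0/False/0 on the first
    three.
    """
    importance = 0
    if (
        taxonomy is not None
        and record.taxon_id is not None
        and record.taxon_id in taxonomy
        and not record.passthrough
    ):
        importance = taxonomy.species_importance(record.taxon_id)
    rep_count = 0
    if store is not None and record.prot_md5 and not record.passthrough:
        rep_count = store.count_by_protein_hash(record.prot_md5)
    return (
        importance,
        record.is_refseq,
        rep_count,
        record.cds_length,
        record.source_length,
        -ordinal,
    )


def select_representative(
    cl: Cluster,
    taxonomy: Optional[TaxonomyDB],
    config: PipelineConfig,
    store: Optional[CDSStore] = None,
) -> Optional[CDSRecord]:
    """Choose the cluster representative.

    Members passing quality control compete on the preference tuple; if
    none passes, ``best_effort`` falls back to the member with the most
    non-ambiguous residues (ties broken by input order) and ``drop``
    leaves the cluster unrepresented.
    """
    passing = [(rec, ordinal) for rec, flags, ordinal in cl.members if flags.passes]
    if not passing:
        if config.empty_cluster_policy == "drop":
            cl.representative = None
            return None
        best = max(
            ((rec, ordinal) for rec, _flags, ordinal in cl.members),
            key=lambda pair: (_ambiguity_score(pair[0], config.output_kind), -pair[1]),
        )
    elif len(passing) == 1:
        best = passing[0]
    else:
        best = max(
            passing,
            key=lambda pair: selection_key(pair[0], pair[1], store, taxonomy),
        )
    cl.representative, cl.representative_ordinal = best
    return best[0]


def run(
    selection: list[SelectorItem],
    config: PipelineConfig,
    store: CDSStore,
    taxonomy: Optional[TaxonomyDB] = None,
) -> tuple[list[CDSRecord], RunReport]:
    """Full pipeline: resolve → expand → cluster → flag → select.

    Returns the ordered representative list plus a stage-by-stage report.
    An empty output is legal; the report says why.
    """
    report = RunReport(items=len(selection))
    resolved_records: list[tuple[CDSRecord, int]] = []
    for item in selection:
        res: Resolution = resolve(item, store, taxonomy)
        if res.matched:
            report.resolved += 1
            for rec in res.matched:
                resolved_records.append((rec, item.input_ordinal))
        elif res.passthrough is not None:
            report.resolved += 1
            report.passthrough += 1
            resolved_records.append((res.passthrough, item.input_ordinal))
        else:
            report.unresolved += 1
            report.unresolved_labels.append(item.raw_label)

    expanded = expand(resolved_records, config.expansion, store)
    report.expanded = len(expanded)

    flagged = [
        (rec, quality_flags(rec, config), ordinal) for rec, ordinal in expanded
    ]
    clusters = cluster(flagged, config.redundancy_key, taxonomy)
    report.clusters = len(clusters)

    output: list[CDSRecord] = []
    for cl in clusters:
        rep = select_representative(cl, taxonomy, config, store)
        if rep is None:
            report.clusters_dropped += 1
        else:
            output.append(rep)
            report.output_ordinals.append(cl.representative_ordinal or 0)
    report.output_records = len(output)
    return output, report
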