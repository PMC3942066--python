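import io
import random
from types import SimpleNamespace

import pytest

from cdskit.fixtures import FixtureSpec, make_genbank, make_taxdump
from cdskit.genbank import CDSRecord
from cdskit.store import CDSStore, build_database
from cdskit.taxonomy import load_taxdump

INGEST_SPEC = FixtureSpec(seed=7, n_entries=90)


@pytest.fixture(scope="session")
def ingest_bundle():
    """Generated flat file + taxdump + built database + ground truth."""
    nodes, names, taxa = make_taxdump(INGEST_SPEC)
    gb_text, truths = make_genbank(INGEST_SPEC)
    store, taxonomy, report = build_database(
        [io.StringIO(gb_text)], io.StringIO(nodes), io.StringIO(names)
    )
    return SimpleNamespace(
        spec=INGEST_SPEC,
        nodes=nodes,
        names=names,
        taxa=taxa,
        gb_text=gb_text,
        truths=truths,
        store=store,
        taxonomy=taxonomy,
        report=report,
    )


@pytest.fixture()
def toy_taxonomy():
    """Fresh toy tree (counters at zero)."""
    nodes, names, _ = make_taxdump(FixtureSpec(seed=0, n_extra_taxa=0))
    return load_taxdump(io.StringIO(nodes), io.StringIO(names))


_POOL_AA = [
    "MKVLITGAGSGIGL",
    "MSYSITTPSQFVFL",
    "MADEEKLPPGWEKR",
    "MTEYKLVVVGAGGV",
    "MGSSHHHHHHSSGL",
]

_CODON = {
    aa: codon
    for aa, codon in zip(
        "ACDEFGHIKLMNPQRSTVWY",
        "GCT TGT GAT GAA TTT GGT CAT ATT AAA CTT ATG AAT CCT CAA CGT TCT ACT GTT TGG TAT".split(),
    )
}


def deterministic_backtranslate(aa: str) -> str:
    return "".join(_CODON[c] for c in aa) + "TAA"


def make_record(
    accession="AAA00001.1",
    taxon_id=9606,
    organism="Homo sapiens",
    aa="MKVLITGAGSGIGL",
    dna=None,
    gi=None,
    partial5=False,
    partial3=False,
    source_length=1000,
    **kw,
):
    """Factory for hand-built CDS records in pipeline/store tests."""
    if dna is None:
        dna = deterministic_backtranslate(aa)
    return CDSRecord(
        protein_accession=accession,
        source_accession="SRC0001.1",
        taxon_id=taxon_id,
        organism=organism,
        dna_seq=dna,
        aa_seq=aa,
        gi=gi,
        partial5=partial5,
        partial3=partial3,
        source_length=source_length,
        **kw,
    )


@pytest.fixture()
def record_factory():
    return make_record


@pytest.fixture()
def scenario_store(toy_taxonomy):
    """The synonymous-CDS scenario: one protein in 3 taxa, 2 CDS in one.

    A (human) and B (mouse) share the same CDS; C (gorilla) has a
    synonymous CDS; D is a second synonymous CDS in human.  All encode
    the identical protein.
    """
    aa = "MKVLITGAGSGIGL"
    dna1 = deterministic_backtranslate(aa)
    # a synonymous variant: swap the leucine codons CTT -> CTG
    dna2 = dna1.replace("CTT", "CTG")
    dna3 = dna1.replace("GGT", "GGC")
    store = CDSStore()
    recs = {
        "A": make_record(accession="AAH00001.1", taxon_id=9606, aa=aa, dna=dna1),
        "B": make_record(
            accession="AAM00002.1",
            taxon_id=10090,
            organism="Mus musculus",
            aa=aa,
            dna=dna1,
        ),
        "C": make_record(
            accession="AAG00003.1",
            taxon_id=9593,
            organism="Gorilla gorilla",
            aa=aa,
            dna=dna2,
        ),
        "D": make_record(accession="AAH00004.1", taxon_id=9606, aa=aa, dna=dna3),
    }
    for rec in recs.values():
        store.put(rec)
        toy_taxonomy.count_cds(rec.taxon_id)
    store.commit()
    return SimpleNamespace(store=store, taxonomy=toy_taxonomy, records=recs)


@pytest.fixture()
def rng():
    return random.Random(20240517)
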