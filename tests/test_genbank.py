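"""Flat-file ingestion: location grammar, partial flags, hashes, round trip."""

import io
import random
from datetime import date

import pytest

from cdskit.genbank import (
    GenBankParseError,
    parse_genbank,
    parse_location,
    partial_flags,
    percent_gc,
    is_refseq,
    reverse_complement,
    sequence_md5,
    splice,
    IngestReport,
)


class TestParseLocation:
    @pytest.mark.parametrize(
        "text,intervals,left_open,right_open",
        [
            ("1..300", [(1, 300, 1)], False, False),
            ("<1..300", [(1, 300, 1)], True, False),
            ("1..>300", [(1, 300, 1)], False, True),
            ("<1..>300", [(1, 300, 1)], True, True),
            ("42", [(42, 42, 1)], False, False),
            ("join(1..6,10..15)", [(1, 6, 1), (10, 15, 1)], False, False),
            ("complement(10..20)", [(10, 20, -1)], False, False),
            # complement flips strand and reverses to coding order
            (
                "complement(join(10..20,30..40))",
                [(30, 40, -1), (10, 20, -1)],
                False,
                False,
            ),
            # join-of-complements lists elements in coding order already
            (
                "join(complement(30..40),complement(10..20))",
                [(30, 40, -1), (10, 20, -1)],
                False,
                False,
            ),
            ("complement(<10..>40)", [(10, 40, -1)], True, True),
        ],
    )
    def test_grammar(self, text, intervals, left_open, right_open):
        loc = parse_location(text)
        assert loc.intervals == intervals
        assert (loc.left_open, loc.right_open) == (left_open, right_open)

    @pytest.mark.parametrize(
        "text",
        [
            "",
            "banana",
            "20..10",
            "order(1..5,10..20)",
            "bond(3,9)",
            "join(1..5,complement(10..20))",
            "join()",
        ],
    )
    def test_rejections(self, text):
        with pytest.raises((GenBankParseError, ValueError)):
            parse_location(text)

    def test_minus_strand_splice_matches_string_oracle(self, rng):
        """Spliced minus-strand CDS == revcomp of plus-strand concatenation."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(50):
            origin = "".join(rng.choice("ACGT") for _ in range(rng.randint(60, 200)))
            a = rng.randint(1, 20)
            b = a + rng.randint(2, 15)
            c = b + rng.randint(2, 10)
            d = c + rng.randint(2, 15)
            loc = parse_location(f"complement(join({a}..{b},{c}..{d}))")
            plus = origin[a - 1 : b] + origin[c - 1 : d]
            oracle = "".join(comp[ch] for ch in reversed(plus))
            assert splice(origin, loc) == oracle


class TestPartialFlags:
    @pytest.mark.parametrize(
        "strand,left,right,expected",
        [
            (1, False, False, (False, False)),
            (1, True, False, (True, False)),
            (1, False, True, (False, True)),
            (1, True, True, (True, True)),
            (-1, False, False, (False, False)),
            (-1, True, False, (False, True)),  # genomic left = 3' on minus
            (-1, False, True, (True, False)),
            (-1, True, True, (True, True)),
        ],
    )
    def test_strand_corrected_grid(self, strand, left, right, expected):
        text = f"{'<' if left else ''}10..{'>' if right else ''}50"
        if strand == -1:
            text = f"complement({text})"
        assert partial_flags(parse_location(text)) == expected


class TestHashesAndStats:
    def test_md5_case_insensitive_and_exact(self):
        assert sequence_md5("acgt") == sequence_md5("ACGT")
        assert sequence_md5("ACGT") != sequence_md5("ACGA")
        # digest of the 4-byte string "ACGT", pinned from an external md5 tool
        assert sequence_md5("ACGT") == "f1f8f4bf413b16ad135722aa4591043e"

    def test_md5_strips_whitespace_and_stop(self):
        assert sequence_md5("MKV LIT\n") == sequence_md5("mkvlit")
        assert sequence_md5("MKVLIT*") == sequence_md5("MKVLIT")

    def test_md5_empty_rejected(self):
        with pytest.raises(ValueError):
            sequence_md5("")

    @pytest.mark.parametrize(
        "dna,expected",
        [("ATGC", 50.0), ("GGCC", 100.0), ("ATAT", 0.0), ("GCS", 100.0)],
    )
    def test_percent_gc(self, dna, expected):
        assert percent_gc(dna) == pytest.approx(expected)

    def test_percent_gc_ambiguity_rule(self):
        # N sits in the denominator only: 2 of 3
        assert percent_gc("GCN") == pytest.approx(66.67, abs=0.01)

    def test_percent_gc_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_gc("")

    @pytest.mark.parametrize(
        "acc,expected",
        [
            ("NP_000509.1", True),
            ("WP_0031.1", True),
            ("XP_123456.2", True),
            ("AAA12345.1", False),
            ("", False),
        ],
    )
    def test_is_refseq(self, acc, expected):
        assert is_refseq(acc) is expected


class TestParseGenBank:
    def test_round_trip_against_ground_truth(self, ingest_bundle):
        """Every parsed field equals what the generator wrote down."""
        truths = {t.protein_accession: t for t in ingest_bundle.truths if t.skip is None}
        parsed = {
            r.protein_accession: r
            for r in parse_genbank(io.StringIO(ingest_bundle.gb_text))
        }
        assert set(parsed) == set(truths)
        for acc, truth in truths.items():
            rec = parsed[acc]
            assert rec.dna_seq == truth.dna_seq
            assert rec.aa_seq == truth.aa_seq
            assert rec.gi == truth.gi
            assert rec.taxon_id == truth.taxon_id
            assert rec.organism == truth.organism
            assert rec.source_accession == truth.source_accession
            assert rec.source_length == truth.source_length
            assert (rec.partial5, rec.partial3) == (truth.partial5, truth.partial3)
            assert rec.gene == truth.gene
            assert rec.product == truth.product
            assert rec.transl_table == truth.transl_table
            assert rec.entry_date == date(2013, 5, 10)
            assert rec.cds_length == len(truth.dna_seq) == rec.location.span

    def test_skip_counts_match_ground_truth(self, ingest_bundle):
        report = IngestReport()
        n = sum(1 for _ in parse_genbank(io.StringIO(ingest_bundle.gb_text), report))
        truths = ingest_bundle.truths
        assert n == sum(1 for t in truths if t.skip is None)
        assert report.pseudo_skipped == sum(1 for t in truths if t.skip == "pseudo")
        assert report.no_translation_skipped == sum(
            1 for t in truths if t.skip == "no_translation"
        )
        assert report.entries_read == ingest_bundle.spec.n_entries

    def test_complete_cds_length_relation(self, ingest_bundle):
        """Complete CDS with an annotated stop: len(dna) == 3*(len(aa)+1)."""
        complete = [
            t
            for t in ingest_bundle.truths
            if t.skip is None and not t.partial5 and not t.partial3
        ]
        assert complete, "fixture grid must include complete CDS"
        for t in complete:
            assert len(t.dna_seq) == 3 * (len(t.aa_seq) + 1)

    def test_agreement_with_biopython(self, ingest_bundle):
        """(accession, taxon, translation, spliced DNA) agree with Bio.SeqIO."""
        SeqIO = pytest.importorskip("Bio.SeqIO")
        ours = {
            r.protein_accession: r
            for r in parse_genbank(io.StringIO(ingest_bundle.gb_text))
        }
        n = 0
        for entry in SeqIO.parse(io.StringIO(ingest_bundle.gb_text), "genbank"):
            taxon = None
            for feat in entry.features:
                if feat.type == "source":
                    for xref in feat.qualifiers.get("db_xref", []):
                        if xref.startswith("taxon:"):
                            taxon = int(xref.split(":")[1])
            for feat in entry.features:
                if feat.type != "CDS" or "translation" not in feat.qualifiers:
                    continue
                acc = feat.qualifiers["protein_id"][0]
                rec = ours[acc]
                assert rec.taxon_id == taxon
                assert rec.aa_seq == feat.qualifiers["translation"][0]
                assert rec.dna_seq == str(feat.extract(entry.seq)).upper()
                n += 1
        assert n == len(ours)

    def test_truncated_entry_raises_with_locus(self):
        text = "LOCUS       BROKEN01                 60 bp    DNA     linear   SYN 10-MAY-2013\nFEATURES             Location/Qualifiers\n"
        with pytest.raises(GenBankParseError, match="BROKEN01"):
            list(parse_genbank(io.StringIO(text)))

    def test_entry_without_origin_skipped(self, ingest_bundle):
        entry = (
            "LOCUS       NOSEQ001                 60 bp    DNA     linear   SYN 10-MAY-2013\n"
            "FEATURES             Location/Qualifiers\n"
            "     source          1..60\n"
            '                     /organism="Homo sapiens"\n'
            '                     /db_xref="taxon:9606"\n'
            "//\n"
        )
        report = IngestReport()
        assert list(parse_genbank(io.StringIO(entry), report)) == []
        assert report.entries_without_sequence == 1
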