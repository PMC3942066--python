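"""Label templating, sanitization/uniqueness, wobble coding, output writing."""

import io
import string
from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from cdskit.formatting import (
    LabelSpec,
    TemplateError,
    build_annotation,
    encode_sequence,
    finalize_labels,
    render,
    ry_recode,
    wobble_ry,
    write_output,
)
from tests.conftest import make_record

PINNED_TODAY = date(2013, 5, 10)


@pytest.fixture()
def human_annotation(toy_taxonomy):
    """A record populated like the hemoglobin-alpha example rows."""
    # 3263 strong bases out of 5000 gives a GC percentage of exactly 65.26
    dna = "G" * 3263 + "A" * 1737
    rec = make_record(
        accession="AAB12345.1",
        taxon_id=9606,
        organism="Homo sapiens",
        gi=450145,
        aa="MVLSPADKTNVKAA",
        dna=dna,
        gene="HBA2",
    )
    return build_annotation(rec, toy_taxonomy, ordinal=1, today=PINNED_TODAY)


class TestBuildAnnotation:
    def test_common_and_scientific_names(self, human_annotation):
        assert human_annotation["ComName"] == "human"
        assert human_annotation["SciName"] == "Homo sapiens"

    def test_genus_and_species_epithet(self, human_annotation):
        assert human_annotation["genus"] == "Homo"
        assert human_annotation["species"] == "sapiens"

    def test_rank_keys_from_lineage(self, human_annotation):
        assert human_annotation["order"] == "Primates"
        assert human_annotation["family"] == "Hominidae"

    def test_common_name_falls_back_to_scientific(self, toy_taxonomy):
        rec = make_record(taxon_id=12110, organism="Foot-and-mouth disease virus")
        ann = build_annotation(rec, toy_taxonomy, ordinal=1)
        assert ann["ComName"] == "Foot-and-mouth disease virus"

    def test_ordinal_and_ids(self, human_annotation):
        assert human_annotation["sqNr"] == 1
        assert human_annotation["gi"] == 450145
        assert human_annotation["taxID"] == 9606
        assert human_annotation["acv"] == "AAB12345.1"
        assert human_annotation["today"] == "2013-05-10"

    def test_absent_values_render_empty(self, toy_taxonomy):
        rec = make_record(gene=None, gi=None)
        ann = build_annotation(rec, toy_taxonomy, ordinal=2)
        assert ann["gene"] == ""
        assert ann["gi"] == ""
        assert render(">%(gene)s", ann) == ">"


class TestRender:
    @pytest.mark.parametrize(
        "template,expected",
        [
            (">%(ComName)s", ">human"),
            (">%(genus).1s%(species)s", ">Hsapiens"),
            (">%(gi)s_%(taxID)s", ">450145_9606"),
            (">seq%(sqNr)s", ">seq1"),
            ("%(pcGC)5.2f", "65.26"),
            ("gene = %(gene)s", "gene = HBA2"),
            ("order = %(order)s", "order = Primates"),
            ("[%(SciName)s]", "[Homo sapiens]"),
            ("%(today)s", "2013-05-10"),
        ],
    )
    def test_table_rows(self, human_annotation, template, expected):
        assert render(template, human_annotation) == expected

    def test_float_width_pads(self, human_annotation):
        assert render("%(pcGC)8.2f", human_annotation) == "   65.26"
        assert render("%(pcGC).0f", human_annotation) == "65"

    def test_unknown_key_renders_empty_with_warning(self, human_annotation, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="cdskit.formatting"):
            assert render("a%(nonsense)sb", human_annotation) == "ab"
        assert any("nonsense" in m for m in caplog.messages)

    def test_literal_percent(self, human_annotation):
        assert render("100%% GC", human_annotation) == "100% GC"

    @pytest.mark.parametrize("template", ["%(x", "%(pcGC)5.2q", "%s"])
    def test_malformed_template_raises_with_position(self, human_annotation, template):
        with pytest.raises(TemplateError, match="position"):
            render(template, human_annotation)


class TestFinalizeLabels:
    def test_duplicate_suffixing(self):
        assert finalize_labels(["human", "human", "human"], LabelSpec()) == [
            "human",
            "human_2",
            "human_3",
        ]

    def test_strict_charset(self):
        spec = LabelSpec(charset_policy="strict")
        assert finalize_labels(["Homo sapiens"], spec) == ["Homo_sapiens"]
        assert finalize_labels([">We|ird(la/bel)"], spec) == [">We_ird_la_bel_"]

    def test_truncation_before_uniquification(self):
        spec = LabelSpec(max_length=5)
        assert finalize_labels(["Hsapiens", "Hsapix"], spec) == ["Hsapi", "Hsapi_2"]

    def test_suffix_collision_with_literal_input(self):
        out = finalize_labels(["a", "a_2", "a"], LabelSpec())
        assert len(set(out)) == 3

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet=string.ascii_letters + " |/(){}", min_size=0, max_size=12),
            max_size=25,
        ),
        st.sampled_from(["strict", "permissive"]),
        st.sampled_from([None, 3, 8]),
    )
    def test_injective_and_order_preserving(self, labels, policy, max_len):
        spec = LabelSpec(charset_policy=policy, max_length=max_len)
        out = finalize_labels(labels, spec)
        assert len(out) == len(labels)
        assert len(set(out)) == len(out)  # injective
        for before, after in zip(labels, out):
            base = before[1:] if before.startswith(">") else before
            if policy == "strict":
                base = "".join(
                    c if c.isalnum() or c in "_.-" else "_" for c in base
                )
            if max_len is not None:
                base = base[:max_len]
            stripped = after[1:] if after.startswith(">") else after
            assert stripped == base or stripped.startswith(base + "_")


class TestSequenceEncoding:
    def test_wobble_third_positions(self):
        assert wobble_ry("ATGGCA") == "ATRGCR"
        assert wobble_ry("ATGGCC") == "ATRGCY"

    def test_wobble_preserves_length_and_is_stable(self, ingest_bundle):
        for rec in list(ingest_bundle.store)[::9]:
            once = wobble_ry(rec.dna_seq)
            assert len(once) == len(rec.dna_seq)
            assert wobble_ry(once) == once
            assert once[: 2] == rec.dna_seq[: 2]

    def test_wobble_ambiguous_base_becomes_n(self):
        assert wobble_ry("ATN") == "ATN"
        assert wobble_ry("AT-") == "ATN"

    def test_full_ry_recode(self):
        assert ry_recode("ATGC") == "RYRY"

    def test_encode_modes(self):
        rec = make_record(aa="MKV", dna="ATGAAAGTTTAA")
        assert encode_sequence(rec, "aa") == "MKV"
        assert encode_sequence(rec, "dna") == "ATGAAAGTTTAA"
        assert encode_sequence(rec, "none") is None
        protein_only = make_record(accession="P1.1", dna="", aa="MKV")
        assert encode_sequence(protein_only, "dna") is None
        assert encode_sequence(protein_only, "aa") == "MKV"


class TestWriteOutput:
    def test_fasta_header_and_wrap(self):
        rec = make_record(dna="A" * 130, aa="MKV")
        buf = io.StringIO()
        write_output([rec], [">human"], ["[Homo sapiens]"], "dna", buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == ">human [Homo sapiens]"
        assert [len(l) for l in lines[1:]] == [60, 60, 10]

    def test_property_file_mode(self):
        rec = make_record()
        buf = io.StringIO()
        write_output([rec], ["human"], ["65.26"], "none", buf)
        assert buf.getvalue() == "human\t65.26\n"

    def test_missing_gt_prepended(self):
        rec = make_record(dna="ATG", aa="M")
        buf = io.StringIO()
        write_output([rec], ["plain"], [""], "dna", buf)
        assert buf.getvalue().startswith(">plain\n")

    def test_dna_mode_skips_protein_passthrough(self):
        rec = make_record(accession="", dna="", aa="MKV", passthrough=True)
        buf = io.StringIO()
        written = write_output([rec], [">x"], [""], "dna", buf)
        assert written == 0
        assert buf.getvalue() == ""

    def test_empty_input_empty_output(self):
        buf = io.StringIO()
        assert write_output([], [], [], "dna", buf) == 0
        assert buf.getvalue() == ""
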