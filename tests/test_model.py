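"""Domain model: header codec, event validation, table and GTF ingestion."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import splicevar as sv
from splicevar.model import HeaderParseError

# fields may contain anything except the header delimiters and whitespace
field_text = st.text(
    alphabet=st.characters(
        codec="ascii", exclude_characters="#():> \t\n\r", min_codepoint=33
    ),
    min_size=1,
    max_size=20,
)


class TestHeaderCodec:
    def test_encode_canonical_form(self):
        tag = sv.HeaderTag("NM_000546", "ES", "SP00123")
        assert sv.encode_header(tag) == "NM_000546# (ES:SP00123)"

    @given(field_text, field_text, field_text)
    def test_round_trip(self, name, code, sid):
        tag = sv.HeaderTag(name, code, sid)
        assert sv.decode_header(sv.encode_header(tag)).tag == tag

    def test_decode_accepts_flexible_spacing_and_leading_marker(self):
        for header in (">NM_1# (ES:SP1)", "NM_1#(ES:SP1)", "NM_1#   (ES:SP1)"):
            assert sv.decode_header(header).tag == sv.HeaderTag("NM_1", "ES", "SP1")

    def test_delimiter_in_field_rejected(self):
        with pytest.raises(ValueError, match="refseq_name"):
            sv.HeaderTag("NM#1", "ES", "SP1")

    def test_reference_header_is_non_variant(self):
        decoded = sv.decode_header("sp|P04637|P53_HUMAN Cellular tumor antigen p53")
        assert not decoded.is_variant
        assert decoded.accession == "sp|P04637|P53_HUMAN"

    def test_malformed_variant_header_errors_with_offset(self):
        with pytest.raises(HeaderParseError) as err:
            sv.decode_header("NM_1# (ES")
        assert err.value.offset == 4


class TestValidateEvent:
    def test_valid_skip_has_no_violations(self, toy_transcript):
        e = sv.SpliceEvent("E1", "NM_1", sv.EventType.EXON_SKIP, {"skip": (1, 1)})
        assert sv.validate_event(toy_transcript, e) == []

    def test_intron_index_out_of_bounds(self, toy_transcript):
        e = sv.SpliceEvent("E1", "NM_1", sv.EventType.INTRON_RETAIN, {"intron": 2})
        violations = sv.validate_event(toy_transcript, e)
        assert len(violations) == 1 and "intron index 2" in violations[0]

    def test_shift_beyond_flank_is_violation(self, toy_transcript):
        e = sv.SpliceEvent("E1", "NM_1", sv.EventType.ALT_3SS, {"exon": 1, "shift": -99})
        assert any("exceeds intron" in v for v in sv.validate_event(toy_transcript, e))

    def test_acceptor_shift_on_exon_zero_rejected(self, toy_transcript):
        e = sv.SpliceEvent("E1", "NM_1", sv.EventType.ALT_3SS, {"exon": 0, "shift": -2})
        assert any("exon 0" in v for v in sv.validate_event(toy_transcript, e))

    def test_combined_overlap_detected(self, toy_transcript):
        a = sv.SpliceEvent("A", "NM_1", sv.EventType.ALT_3SS, {"exon": 1, "shift": -2})
        b = sv.SpliceEvent("B", "NM_1", sv.EventType.ALT_3SS, {"exon": 1, "shift": 2})
        c = sv.CombinedEvent("C", "NM_1", (a, b))
        assert any("overlap" in v for v in sv.validate_event(toy_transcript, c))

    def test_dual_specific_cannot_be_applied(self, toy_transcript):
        e = sv.SpliceEvent("E1", "NM_1", sv.EventType.DUAL_SPECIFIC, {})
        assert any("DUAL_SPECIFIC" in v for v in sv.validate_event(toy_transcript, e))


class TestTranscriptInvariants:
    def test_intron_count_must_match(self):
        with pytest.raises(ValueError, match="introns"):
            sv.Transcript("T", "G", ("ATG", "TAA"), (), 0)

    def test_cds_length_multiple_of_three(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            sv.Transcript("T", "G", ("ATGAA",), (), 0, 5)

    def test_non_nucleotide_rejected_but_n_allowed(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            sv.Transcript("T", "G", ("ATGQ",), (), 0)
        t = sv.Transcript("T", "G", ("ATGNNN",), (), 0, 6)
        assert t.mrna == "ATGNNN"


class TestTables:
    def test_event_table_round_trip(self, tmp_path, toy_transcript):
        events = [
            sv.SpliceEvent("E1", "NM_1", sv.EventType.EXON_SKIP, {"skip": (1, 1)}, 3),
            sv.SpliceEvent("E2", "NM_1", sv.EventType.ALT_3SS, {"exon": 1, "shift": -4}, 2),
            sv.SpliceEvent("E3", "NM_1", sv.EventType.INTRON_RETAIN, {"intron": 0}, 5),
            sv.CombinedEvent(
                "E4",
                "NM_1",
                (
                    sv.SpliceEvent("E4.0", "NM_1", sv.EventType.EXON_SKIP, {"skip": (1, 1)}, 4),
                    sv.SpliceEvent("E4.1", "NM_1", sv.EventType.INTRON_RETAIN, {"intron": 1}, 4),
                ),
                4,
            ),
        ]
        path = tmp_path / "events.tsv"
        sv.write_event_table(events, path)
        back = sv.read_event_table(path)
        assert back == events

    def test_transcript_pair_round_trip(self, tmp_path, toy_transcript):
        tsv, fasta = tmp_path / "t.tsv", tmp_path / "t.fasta"
        sv.write_transcripts([toy_transcript], tsv, fasta)
        back = sv.read_transcripts(tsv, fasta)
        assert back["NM_1"] == toy_transcript

    def test_missing_header_line_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("E1\tNM_1\tEXON_SKIP\tskip=1-1\t2\n")
        with pytest.raises(ValueError, match="header"):
            sv.read_event_table(path)


class TestGtfIngestion:
    GENOME = ">chr1\n" + "".join(
        # exon1(10) intron1(8) exon2(9) intron2(6) exon3(12) with CDS inside
        "CCCCATGGCA" "GTAAGTAG" "GAATTCAAA" "GTCAGT" "TTATAAGGGCCC"
    ) + "\n"

    GTF_PLUS = "\n".join(
        [
            'chr1\tx\texon\t1\t10\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
            'chr1\tx\texon\t19\t27\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
            'chr1\tx\texon\t34\t45\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
            'chr1\tx\tCDS\t5\t10\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
            'chr1\tx\tCDS\t19\t27\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
            'chr1\tx\tCDS\t34\t39\t.\t+\t.\tgene_id "G1"; transcript_id "T1";',
        ]
    ) + "\n"

    def test_plus_strand(self, tmp_path):
        (tmp_path / "g.fa").write_text(self.GENOME)
        (tmp_path / "m.gtf").write_text(self.GTF_PLUS)
        t = sv.transcripts_from_gtf(tmp_path / "m.gtf", tmp_path / "g.fa")["T1"]
        assert t.exons == ("CCCCATGGCA", "GAATTCAAA", "TTATAAGGGCCC")
        assert t.introns == ("GTAAGTAG", "GTCAGT")
        assert t.cds_start == 4
        assert t.mrna[t.cds_start : t.cds_start + 3] == "ATG"
        assert (t.cds_end - t.cds_start) % 3 == 0

    def test_minus_strand_reverse_complements(self, tmp_path):
        # same gene laid on the minus strand: reverse-complement the genome
        from Bio.Seq import Seq

        plus = self.GENOME.splitlines()[1]
        (tmp_path / "g.fa").write_text(">chr1\n" + str(Seq(plus).reverse_complement()) + "\n")
        L = len(plus)

        def flip(a, b):
            return L - b + 1, L - a + 1

        rows = []
        for line in self.GTF_PLUS.strip().splitlines():
            f = line.split("\t")
            a, b = flip(int(f[3]), int(f[4]))
            rows.append("\t".join([f[0], f[1], f[2], str(a), str(b), f[5], "-", f[7], f[8]]))
        (tmp_path / "m.gtf").write_text("\n".join(rows) + "\n")
        t = sv.transcripts_from_gtf(tmp_path / "m.gtf", tmp_path / "g.fa")["T1"]
        assert t.exons == ("CCCCATGGCA", "GAATTCAAA", "TTATAAGGGCCC")
        assert t.introns == ("GTAAGTAG", "GTCAGT")
        assert t.cds_start == 4
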