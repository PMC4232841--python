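"""Splice engine: worked examples, coordinate maps, and block-edit oracle
equivalence on randomized transcripts and events."""

import numpy as np
import pytest

import splicevar as sv
from splicevar.simulate import _oracle_variant
from conftest import random_combined, random_event, random_transcript


class TestExamples:
    def test_reference_is_exon_concatenation(self, toy_transcript):
        assert sv.splice_reference(toy_transcript) == "ATGGCAGAATTCTAA"
        single = sv.Transcript("T", "G", ("ATG",), (), 0)
        assert sv.splice_reference(single) == "ATG"

    def test_exon_skip_removes_middle_block(self, toy_transcript):
        e = sv.SpliceEvent("E", "NM_1", sv.EventType.EXON_SKIP, {"skip": (1, 1)})
        vt = sv.apply_event(toy_transcript, e)
        assert vt.sequence == "ATGGCATAA"
        assert vt.modified_regions == ((6, 6),)  # zero-length junction mark

    def test_intron_retention_inserts(self):
        t = sv.Transcript("T", "G", ("ATGAAA", "TAA"), ("GGG",), 0, 9)
        e = sv.SpliceEvent("E", "T", sv.EventType.INTRON_RETAIN, {"intron": 0})
        vt = sv.apply_event(t, e)
        assert vt.sequence == "ATGAAAGGGTAA"
        assert vt.modified_regions == ((6, 9),)

    def test_acceptor_truncation(self):
        t = sv.Transcript("T", "G", ("ATGAAA", "CCCTAA"), ("GTGTGT",), 0, 12)
        e = sv.SpliceEvent("E", "T", sv.EventType.ALT_3SS, {"exon": 1, "shift": 3})
        assert sv.apply_event(t, e).sequence == "ATGAAATAA"

    def test_acceptor_extension_marks_inserted_region(self):
        t = sv.Transcript("T", "G", ("ATGAAA", "CCCTAA"), ("GTGTGT",), 0, 12)
        e = sv.SpliceEvent("E", "T", sv.EventType.ALT_3SS, {"exon": 1, "shift": -2})
        vt = sv.apply_event(t, e)
        assert vt.sequence == "ATGAAAGTCCCTAA"
        assert vt.modified_regions == ((6, 8),)

    def test_donor_shift_is_symmetric(self):
        t = sv.Transcript("T", "G", ("ATGAAA", "CCCTAA"), ("GTGTGT",), 0, 12)
        ext = sv.SpliceEvent("E", "T", sv.EventType.ALT_5SS, {"exon": 0, "shift": 2})
        assert sv.apply_event(t, ext).sequence == "ATGAAAGTCCCTAA"
        trunc = sv.SpliceEvent("E", "T", sv.EventType.ALT_5SS, {"exon": 0, "shift": -3})
        assert sv.apply_event(t, trunc).sequence == "ATGCCCTAA"


class TestCoordinateMap:
    def test_skip_mapping_and_unmapped_interior(self):
        t = sv.Transcript("T", "G", ("ATGGCA", "GAATTC", "TAA"), ("GT", "AG"), 0, 15)
        e = sv.SpliceEvent("E", "T", sv.EventType.EXON_SKIP, {"skip": (1, 1)})
        vt = sv.apply_event(t, e)
        assert sv.map_position(vt, 0) == 0
        assert sv.map_position(vt, 12) == 6
        assert sv.map_position(vt, 7) is None
        unmapped = {p for p in range(15) if vt.coord_map[p] is None}
        assert unmapped == set(range(6, 12))

    def test_out_of_range_position_raises(self, toy_transcript):
        e = sv.SpliceEvent("E", "NM_1", sv.EventType.EXON_SKIP, {"skip": (1, 1)})
        vt = sv.apply_event(toy_transcript, e)
        with pytest.raises(IndexError):
            sv.map_position(vt, 15)

    def test_identity_for_unmodified_positions(self, toy_transcript):
        e = sv.SpliceEvent("E", "NM_1", sv.EventType.INTRON_RETAIN, {"intron": 1})
        vt = sv.apply_event(toy_transcript, e)
        for p in range(12):
            assert vt.coord_map[p] == p
        for p in range(12, 15):
            assert vt.coord_map[p] == p + len(toy_transcript.introns[1])


class TestCombined:
    def test_skip_plus_retention_single_pass(self):
        t = sv.Transcript(
            "T", "G", ("ATGGCA", "GAATTC", "CCGGTT", "TAA"), ("GT", "AG", "CA"), 0
        )
        c = sv.CombinedEvent(
            "C",
            "T",
            (
                sv.SpliceEvent("C.0", "T", sv.EventType.EXON_SKIP, {"skip": (1, 1)}),
                sv.SpliceEvent("C.1", "T", sv.EventType.INTRON_RETAIN, {"intron": 2}),
            ),
        )
        vt = sv.apply_combined(t, c)
        assert vt.sequence == "ATGGCA" + "CCGGTT" + "CA" + "TAA"
        seq, coord, regions = _oracle_variant(t, c.events)
        assert (vt.sequence, list(vt.coord_map), vt.modified_regions) == (
            seq, coord, regions,
        )

    def test_singleton_equivalence(self, toy_transcript):
        e = sv.SpliceEvent("C.0", "NM_1", sv.EventType.INTRON_RETAIN, {"intron": 0})
        vt1 = sv.apply_event(toy_transcript, e)
        # a CombinedEvent must have >= 2 constituents, so compare via _apply
        from splicevar.splicing import _apply

        vt2 = _apply(toy_transcript, (e,), "C")
        assert vt1.sequence == vt2.sequence
        assert vt1.coord_map == vt2.coord_map

    def test_adjacent_skips_equal_range_skip(self):
        t = sv.Transcript(
            "T", "G", ("ATGGCA", "GAATTC", "CCGGTT", "TAA"), ("GT", "AG", "CA"), 0
        )
        c = sv.CombinedEvent(
            "C",
            "T",
            (
                sv.SpliceEvent("C.0", "T", sv.EventType.EXON_SKIP, {"skip": (1, 1)}),
                sv.SpliceEvent("C.1", "T", sv.EventType.EXON_SKIP, {"skip": (2, 2)}),
            ),
        )
        single = sv.SpliceEvent("S", "T", sv.EventType.EXON_SKIP, {"skip": (1, 2)})
        a = sv.apply_combined(t, c)
        b = sv.apply_event(t, single)
        assert a.sequence == b.sequence
        assert a.coord_map == b.coord_map
        assert a.modified_regions == b.modified_regions

    def test_overlapping_constituents_rejected(self, toy_transcript):
        c = sv.CombinedEvent(
            "C",
            "NM_1",
            (
                sv.SpliceEvent("C.0", "NM_1", sv.EventType.EXON_SKIP, {"skip": (1, 1)}),
                sv.SpliceEvent("C.1", "NM_1", sv.EventType.ALT_3SS, {"exon": 1, "shift": 2}),
            ),
        )
        with pytest.raises(ValueError, match="overlap"):
            sv.apply_combined(toy_transcript, c)


class TestOracleEquivalence:
    """Randomized cross-validation against the independent token-stream
    block rewriter, plus the length and monotonicity invariants."""

    def test_simple_events_match_oracle(self):
        rng = np.random.default_rng(11)
        for k in range(150):
            t = random_transcript(rng)
            e = random_event(rng, t, f"E{k}")
            vt = sv.apply_event(t, e)
            seq, coord, regions = _oracle_variant(t, (e,))
            assert vt.sequence == seq
            assert list(vt.coord_map) == coord
            assert vt.modified_regions == regions

    def test_combined_events_match_oracle(self):
        rng = np.random.default_rng(12)
        done = 0
        for k in range(200):
            t = random_transcript(rng)
            c = random_combined(rng, t, f"C{k}")
            if c is None:
                continue
            vt = sv.apply_combined(t, c)
            seq, coord, regions = _oracle_variant(t, c.events)
            assert vt.sequence == seq
            assert list(vt.coord_map) == coord
            assert vt.modified_regions == regions
            done += 1
        assert done >= 100

    def test_length_bookkeeping_and_monotonicity(self):
        rng = np.random.default_rng(13)
        for k in range(150):
            t = random_transcript(rng)
            e = random_event(rng, t, f"E{k}")
            vt = sv.apply_event(t, e)
            insertions = sum(b - a for a, b in vt.modified_regions)
            deletions = sum(1 for p in vt.coord_map if p is None)
            assert len(vt.sequence) == t.spliced_length + insertions - deletions
            mapped = [p for p in vt.coord_map if p is not None]
            assert mapped == sorted(set(mapped))
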