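"""Tryptic digestion: cleavage rule (no proline restriction), missed
cleavages, indexing, variant uniqueness, and two independent oracles."""

import numpy as np
import pytest

import splicevar as sv
from splicevar.digest import DigestParameterMismatch, DigestParams
from splicevar.simulate import _oracle_peptides


def _random_protein(rng, n):
    # weighted toward K/R so peptides stay short
    alphabet = list("ACDEFGHILMNPQSTVWY") + ["K"] * 4 + ["R"] * 4
    return "M" + "".join(rng.choice(alphabet, size=n - 1))


class TestCleavageSites:
    def test_cuts_before_proline(self):
        assert sv.cleavage_sites("SAMPLEKPEPTIDER") == [7]
        peps = {p.sequence for p in sv.digest("SAMPLEKPEPTIDER", min_length=1)}
        assert {"SAMPLEK", "PEPTIDER"} <= peps

    def test_no_sites_without_kr(self):
        assert sv.cleavage_sites("AAAA") == []

    def test_consecutive_basic_residues(self):
        assert sv.cleavage_sites("KRKR") == [1, 2, 3]


class TestDigest:
    def test_worked_example_two_missed_min_seven(self):
        peps = {p.sequence for p in sv.digest("MKAGRDEFGHIKLMNPK")}
        assert peps == {
            "DEFGHIK",
            "AGRDEFGHIK",
            "DEFGHIKLMNPK",
            "MKAGRDEFGHIK",
            "AGRDEFGHIKLMNPK",
        }

    def test_terminal_lysine_is_not_a_site(self):
        # the C-terminal residue never opens a new peptide
        peps = sv.digest("MK", max_missed=0, min_length=1)
        assert [p.sequence for p in peps] == ["MK"]
        with_met = sv.digest("MK", max_missed=0, min_length=1, met_removed=True)
        assert {p.sequence for p in with_met} == {"MK", "K"}
        assert [p.met_removed for p in with_met if p.sequence == "K"] == [True]

    def test_protein_without_sites_is_one_peptide(self):
        assert [p.sequence for p in sv.digest("MAAAAAAA")] == ["MAAAAAAA"]
        assert sv.digest("MAA") == []

    def test_positions_and_missed_counts(self):
        peps = sv.digest("MKAGRDEFGHIKLMNPK", min_length=1)
        by_seq = {p.sequence: p for p in peps}
        assert by_seq["MK"].start_pos == 1 and by_seq["MK"].missed_cleavages == 0
        assert by_seq["AGR"].start_pos == 3
        assert by_seq["MKAGRDEFGHIK"].missed_cleavages == 2

    def test_oracle_equivalence_on_random_proteins(self):
        rng = np.random.default_rng(31)
        for _ in range(120):
            prot = _random_protein(rng, int(rng.integers(8, 200)))
            missed = int(rng.integers(0, 3))
            min_len = int(rng.integers(1, 9))
            mine = {p.sequence for p in sv.digest(prot, missed, min_len)}
            assert mine == _oracle_peptides(prot, missed, min_len)

    def test_pyteomics_cross_check(self):
        pytest.importorskip("pyteomics")
        from pyteomics import parser

        rng = np.random.default_rng(32)
        for _ in range(40):
            prot = _random_protein(rng, int(rng.integers(8, 120)))
            mine = {p.sequence for p in sv.digest(prot, max_missed=2, min_length=1)}
            theirs = parser.cleave(prot, rule=r"(?<=[KR])", missed_cleavages=2, min_length=1)
            assert mine == set(theirs)

    def test_conservation_at_zero_missed(self):
        rng = np.random.default_rng(33)
        for _ in range(40):
            prot = _random_protein(rng, int(rng.integers(5, 100)))
            frags = [
                p.sequence
                for p in sv.digest(prot, max_missed=0, min_length=1)
            ]
            assert "".join(frags) == prot


class TestPeptideIndex:
    def test_single_protein_index_keys_equal_digest(self):
        prot = "MKAGRDEFGHIKLMNPK"
        idx = sv.build_peptide_index([("P1", prot)])
        assert set(idx.mapping) == {p.sequence for p in sv.digest(prot)}

    def test_shared_peptide_tracks_both_accessions(self):
        idx = sv.build_peptide_index(
            [("P1", "MKAAADEFGHIK"), ("P2", "MCCCKAAADEFGHIK")], DigestParams()
        )
        assert {a for a, _ in idx.occurrences("AAADEFGHIK")} == {"P1", "P2"}

    def test_empty_proteome_and_duplicate_accession(self):
        assert len(sv.build_peptide_index([])) == 0
        with pytest.raises(ValueError, match="duplicate"):
            sv.build_peptide_index([("P1", "MAAAK"), ("P1", "MCCCK")])

    def test_il_equivalence_folds_before_lookup(self):
        idx = sv.build_peptide_index(
            [("P1", "MAAAILAAK")], DigestParams(il_equivalence=True)
        )
        assert "MAAALIAAK" in idx
        strict = sv.build_peptide_index([("P1", "MAAAILAAK")])
        assert "MAAALIAAK" not in strict


class TestVariantUnique:
    REF = "MAAEEFFKGGHHIIKLLMMNNR"
    VAR = "MAAKGGHHIIKLLMMNNR"

    def _variant(self):
        # transcript whose CDS encodes REF; skipping exon 1 encodes VAR
        from splicevar.model import EventType

        codon = {
            "M": "ATG", "A": "GCA", "E": "GAA", "F": "TTT", "K": "AAA",
            "G": "GGA", "H": "CAT", "I": "ATT", "L": "CTG", "N": "AAT", "R": "AGA",
        }
        cds = "".join(codon[aa] for aa in self.REF) + "TAA"
        exon0 = cds[:9]  # MAA
        exon1 = cds[9:21]  # EEFF
        exon2 = cds[21:]
        t = sv.Transcript("NM_9", "G9", (exon0, exon1, exon2), ("GT", "AG"), 0, len(cds))
        e = sv.SpliceEvent("EV9", "NM_9", EventType.EXON_SKIP, {"skip": (1, 1)})
        return t, e

    def test_unique_set_matches_brute_force(self):
        t, e = self._variant()
        v = sv.predict_variant_protein(t, e)
        assert (v.reference_protein, v.sequence) == (self.REF, self.VAR)
        idx = sv.build_peptide_index([("P1", self.REF)])
        unique = {p.sequence for p in sv.variant_unique_peptides(v, idx)}
        assert unique == {"MAAKGGHHIIK", "MAAKGGHHIIKLLMMNNR"}
        brute = _oracle_peptides(self.VAR) - _oracle_peptides(self.REF)
        assert unique == brute

    def test_identical_variant_has_no_unique_peptides(self):
        t, e = self._variant()
        v = sv.predict_variant_protein(t, e)
        idx = sv.build_peptide_index([("P1", self.VAR)])
        assert sv.variant_unique_peptides(v, idx) == []

    def test_parameter_mismatch_raises(self):
        t, e = self._variant()
        v = sv.predict_variant_protein(t, e)
        idx = sv.build_peptide_index([("P1", self.REF)], DigestParams(max_missed=1))
        with pytest.raises(DigestParameterMismatch):
            sv.variant_unique_peptides(v, idx, params=DigestParams(max_missed=2))

    def test_unique_peptides_absent_from_index_and_present_in_digest(self):
        t, e = self._variant()
        v = sv.predict_variant_protein(t, e)
        idx = sv.build_peptide_index([("P1", self.REF)])
        digest_set = {p.sequence for p in sv.digest(v.sequence)}
        for p in sv.variant_unique_peptides(v, idx):
            assert p.sequence not in idx
            assert p.sequence in digest_set
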