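"""Largest-ORF prediction and translation.

ORFs are ATG-initiated only and extend to the first in-frame stop codon
(TAA/TAG/TGA).  ``largest_orf`` picks the longest ORF in nucleotides; ties
go to the 5'-most start.  Open-ended ORFs (no stop before the sequence
end) are excluded by default — a predicted full-length cDNA is expected to
encode a complete ORF — but can be admitted with ``allow_open_ended``.

Codons containing N translate to X and never terminate an ORF; only exact
stop codons do.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

__all__ = ["Orf", "enumerate_orfs", "largest_orf", "translate", "STOP_CODONS"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_TABLE = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)


@dataclass(frozen=True)
class Orf:
    start: int  # offset of the A of ATG
    end: int  # exclusive offset of the last base of the final codon
    has_stop: bool

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def enumerate_orfs(seq: str) -> list[Orf]:
    """One ORF per ATG occurrence, extended to the first in-frame stop or,
    failing that, to the last complete codon before the sequence end."""
    seq = seq.upper()
    orfs: list[Orf] = []
    start = seq.find("ATG")
    while start != -1:
        end = start + 3
        has_stop = False
        pos = start + 3
        while pos + 3 <= len(seq):
            codon = seq[pos : pos + 3]
            end = pos + 3
            if codon in STOP_CODONS:
                has_stop = True
                break
            pos += 3
        orfs.append(Orf(start=start, end=end, has_stop=has_stop))
        start = seq.find("ATG", start + 1)
    return orfs


def largest_orf(seq: str, allow_open_ended: bool = False) -> Orf | None:
    """Longest ORF by nucleotide length (stop codon included); ties break
    to the smallest start.  Returns ``None`` when no eligible ORF exists."""
    candidates = [o for o in enumerate_orfs(seq) if o.has_stop or allow_open_ended]
    if not candidates:
        return None
    return min(candidates, key=lambda o: (-o.length_nt, o.start))


def translate(seq: str, orf: Orf) -> str:
    """Standard-code translation of an ORF, stop codon excluded; codons
    containing N yield X."""
    seq = seq.upper()
    if orf.end > len(seq) or orf.start < 0:
        raise ValueError(f"ORF {orf.start}..{orf.end} outside sequence of length {len(seq)}")
    if (orf.end - orf.start) % 3:
        raise ValueError(f"ORF {orf.start}..{orf.end} is not a whole number of codons")
    if seq[orf.start : orf.start + 3] != "ATG":
        raise ValueError(f"ORF at {orf.start} does not begin with ATG")
    stop_trim = 3 if orf.has_stop else 0
    residues = []
    for pos in range(orf.start, orf.end - stop_trim, 3):
        codon = seq[pos : pos + 3]
        residues.append(_TABLE.get(codon, "X"))
    return "".join(residues)
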