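"""In-silico tryptic digestion and peptide-to-proteome indexing.

Cleavage is C-terminal to K or R with *no proline restriction* (K|P and
R|P bonds are cut too).  Defaults match the search settings the pipeline
emulates: at most two missed cleavages, minimum peptide length 7.

A :class:`PeptideIndex` maps every tryptic peptide of a proteome to the
(accession, start) pairs where it occurs; variant-uniqueness is defined on
this tryptic universe — a variant peptide "exists" in the reference
proteome only if it is itself a tryptic product there.  The stricter
substring mode additionally rejects peptides found anywhere inside the
variant's own template protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from .database import VariantProtein

__all__ = [
    "TrypticPeptide",
    "DigestParams",
    "PeptideIndex",
    "DigestParameterMismatch",
    "cleavage_sites",
    "digest",
    "build_peptide_index",
    "variant_unique_peptides",
]


class DigestParameterMismatch(ValueError):
    pass


@dataclass(frozen=True)
class DigestParams:
    max_missed: int = 2
    min_length: int = 7
    il_equivalence: bool = False
    met_removed: bool = False  # also emit Met-cleaved N-terminal peptides

    def fold(self, peptide: str) -> str:
        return peptide.replace("I", "L") if self.il_equivalence else peptide


@dataclass(frozen=True)
class TrypticPeptide:
    sequence: str
    protein_accession: str
    start_pos: int  # 1-based residue position in the protein
    missed_cleavages: int
    met_removed: bool = False


def cleavage_sites(protein: str) -> list[int]:
    """1-based positions after which trypsin cuts (after every K/R,
    including before P; the C-terminal residue is never a site)."""
    return [i + 1 for i, aa in enumerate(protein[:-1]) if aa in "KR"]


def digest(
    protein: str,
    max_missed: int = 2,
    min_length: int = 7,
    accession: str = "",
    met_removed: bool = False,
) -> list[TrypticPeptide]:
    """All tryptic peptides with at most ``max_missed`` internal sites and
    length >= ``min_length``, sorted by start position then length.

    With ``met_removed``, each N-terminal peptide of a Met-initiated
    protein is also emitted in its Met-cleaved form (start position 2).
    """
    bounds = [0] + cleavage_sites(protein) + [len(protein)]
    peptides: list[TrypticPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(bounds))):
            seq = protein[bounds[i] : bounds[j]]
            if len(seq) < min_length:
                continue
            peptides.append(
                TrypticPeptide(
                    sequence=seq,
                    protein_accession=accession,
                    start_pos=bounds[i] + 1,
                    missed_cleavages=j - i - 1,
                )
            )
            if met_removed and bounds[i] == 0 and protein.startswith("M") and len(seq) - 1 >= min_length:
                peptides.append(
                    TrypticPeptide(
                        sequence=seq[1:],
                        protein_accession=accession,
                        start_pos=2,
                        missed_cleavages=j - i - 1,
                        met_removed=True,
                    )
                )
    peptides.sort(key=lambda p: (p.start_pos, len(p.sequence)))
    return peptides


@dataclass
class PeptideIndex:
    params: DigestParams
    source: str = ""
    mapping: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    n_proteins: int = 0

    def add(self, accession: str, protein: str) -> None:
        for p in digest(
            protein,
            max_missed=self.params.max_missed,
            min_length=self.params.min_length,
            accession=accession,
            met_removed=self.params.met_removed,
        ):
            self.mapping.setdefault(self.params.fold(p.sequence), set()).add(
                (accession, p.start_pos)
            )
        self.n_proteins += 1

    def __contains__(self, peptide: str) -> bool:
        return self.params.fold(peptide) in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def occurrences(self, peptide: str) -> set[tuple[str, int]]:
        return self.mapping.get(self.params.fold(peptide), set())


def build_peptide_index(
    proteome: Iterable[tuple[str, str]],
    params: DigestParams | None = None,
    source: str = "",
) -> PeptideIndex:
    """Index a proteome given as (accession, sequence) pairs; duplicate
    accessions are an error."""
    index = PeptideIndex(params=params or DigestParams(), source=source)
    seen: set[str] = set()
    for accession, sequence in proteome:
        if accession in seen:
            raise ValueError(f"duplicate accession in proteome: {accession}")
        seen.add(accession)
        index.add(accession, sequence)
    return index


def variant_unique_peptides(
    v: "VariantProtein",
    reference_index: PeptideIndex,
    params: DigestParams | None = None,
    template_substring: bool = False,
) -> list[TrypticPeptide]:
    """Tryptic peptides of a variant protein absent from the reference
    tryptic universe.

    ``template_substring`` enables the stricter mode that also drops
    peptides occurring anywhere inside the variant's template reference
    protein (semi-tryptic coincidences).
    """
    if params is not None and params != reference_index.params:
        raise DigestParameterMismatch(
            f"digestion parameters {params} differ from index parameters "
            f"{reference_index.params}"
        )
    params = reference_index.params
    unique = []
    for p in digest(
        v.sequence,
        max_missed=params.max_missed,
        min_length=params.min_length,
        accession=v.accession,
        met_removed=params.met_removed,
    ):
        if p.sequence in reference_index:
            continue
        if template_substring and p.sequence in v.reference_protein:
            continue
        unique.append(p)
    return unique
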