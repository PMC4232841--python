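"""Variant protein prediction and search-database construction.

``predict_variant_protein`` composes the splice engine, largest-ORF
prediction and translation, keeping only products whose amino-acid
sequence actually differs from the template's reference protein.

``build_database`` runs the prediction over an event set, filters by
support count, de-duplicates identical variant sequences, tags each
surviving record with its ``NAME# (TYPE:ID)`` header and appends the
reference proteome verbatim — producing the merged FASTA a search engine
would consume, plus a build report accounting for every input event.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .model import (
    DEFAULT_EVENT_CODES,
    CombinedEvent,
    Event,
    HeaderTag,
    SpliceEvent,
    Transcript,
    encode_header,
)
from .orf import Orf, largest_orf, translate
from .splicing import VariantTranscript, apply_combined, apply_event

__all__ = [
    "VariantProtein",
    "BuildReport",
    "VariantDatabase",
    "reference_protein",
    "predict_variant_protein",
    "build_database",
    "read_reference_fasta",
]


def reference_protein(t: Transcript) -> str:
    """Translation of the transcript's annotated CDS (to the annotated end,
    or to the first in-frame stop when ``cds_end`` is absent)."""
    mrna = t.mrna
    if t.cds_end is not None:
        orf = Orf(start=t.cds_start, end=t.cds_end, has_stop=True)
        # annotated CDS may or may not include the stop codon
        last = mrna[t.cds_end - 3 : t.cds_end]
        if last not in {"TAA", "TAG", "TGA"}:
            orf = Orf(start=t.cds_start, end=t.cds_end, has_stop=False)
        return translate(mrna, orf)
    end = t.cds_start + 3
    pos = t.cds_start + 3
    has_stop = False
    while pos + 3 <= len(mrna):
        end = pos + 3
        if mrna[pos : pos + 3] in {"TAA", "TAG", "TGA"}:
            has_stop = True
            break
        pos += 3
    return translate(mrna, Orf(start=t.cds_start, end=end, has_stop=has_stop))


@dataclass(frozen=True)
class VariantProtein:
    """Largest-ORF product of a variant mRNA, with full provenance.

    Carries everything TIS classification needs: the variant mRNA, the ORF
    coordinates, the reference→variant coordinate map and the modified
    regions, plus the template's reference protein and CDS start.
    """

    sequence: str
    tag: HeaderTag
    tis_mrna_offset: int
    orf: Orf
    mrna: str
    reference_protein: str
    reference_cds_start: int
    event_ref: str
    event_type_code: str
    modified_regions: tuple[tuple[int, int], ...]
    coord_map: tuple[int | None, ...]
    merged_event_ids: tuple[str, ...] = ()

    @property
    def accession(self) -> str:
        return encode_header(self.tag)


def event_type_code(e: Event, codes: Mapping[str, str] = DEFAULT_EVENT_CODES) -> str:
    if isinstance(e, CombinedEvent):
        inner = "+".join(codes[sub.event_type.value] for sub in e.events)
        return f"{codes['COMBINED']}({inner})"
    return codes[e.event_type.value]


def predict_variant_protein(
    t: Transcript,
    e: Event,
    allow_open_ended: bool = False,
    codes: Mapping[str, str] = DEFAULT_EVENT_CODES,
) -> VariantProtein | None:
    """Variant protein for one event, or ``None`` when the variant mRNA has
    no eligible ORF or its product equals the reference protein."""
    if isinstance(e, CombinedEvent):
        vt = apply_combined(t, e)
    else:
        vt = apply_event(t, e)
    orf = largest_orf(vt.sequence, allow_open_ended=allow_open_ended)
    if orf is None:
        return None
    protein = translate(vt.sequence, orf)
    ref = reference_protein(t)
    if protein == ref:
        return None
    code = event_type_code(e, codes)
    # the header tag uses the bare combined-event code: parentheses are
    # delimiters in the header grammar
    tag_code = codes["COMBINED"] if isinstance(e, CombinedEvent) else code
    return VariantProtein(
        sequence=protein,
        tag=HeaderTag(refseq_name=t.transcript_id, event_type_code=tag_code, splooce_id=e.event_id),
        tis_mrna_offset=orf.start,
        orf=orf,
        mrna=vt.sequence,
        reference_protein=ref,
        reference_cds_start=t.cds_start,
        event_ref=e.event_id,
        event_type_code=code,
        modified_regions=vt.modified_regions,
        coord_map=vt.coord_map,
        merged_event_ids=(e.event_id,),
    )


@dataclass
class BuildReport:
    n_events: int = 0
    n_kept: int = 0
    n_below_support: int = 0
    n_no_orf: int = 0
    n_identical: int = 0
    n_deduped: int = 0
    n_reference_records: int = 0
    merged: dict[str, tuple[str, ...]] = field(default_factory=dict)  # kept id -> all ids
    reference_collisions: list[str] = field(default_factory=list)

    @property
    def n_variant_records(self) -> int:
        return self.n_kept - self.n_deduped

    @property
    def n_total_records(self) -> int:
        return self.n_variant_records + self.n_reference_records

    def to_tsv(self) -> str:
        rows = [
            ("n_events", self.n_events),
            ("n_kept", self.n_kept),
            ("n_below_support", self.n_below_support),
            ("n_no_orf", self.n_no_orf),
            ("n_identical", self.n_identical),
            ("n_deduped", self.n_deduped),
            ("n_variant_records", self.n_variant_records),
            ("n_reference_records", self.n_reference_records),
            ("n_total_records", self.n_total_records),
        ]
        lines = ["metric\tvalue"] + [f"{k}\t{v}" for k, v in rows]
        for kept, ids in sorted(self.merged.items()):
            lines.append(f"merged:{kept}\t{','.join(ids)}")
        for acc in self.reference_collisions:
            lines.append(f"reference_collision\t{acc}")
        return "\n".join(lines) + "\n"


@dataclass
class VariantDatabase:
    variants: list[VariantProtein]
    reference_records: list[tuple[str, str]]  # (verbatim header, sequence)
    report: BuildReport
    events: dict[str, Event] = field(default_factory=dict)

    def variant_by_accession(self) -> dict[str, VariantProtein]:
        return {v.accession: v for v in self.variants}

    def variant_by_event(self) -> dict[str, VariantProtein]:
        out: dict[str, VariantProtein] = {}
        for v in self.variants:
            for eid in v.merged_event_ids:
                out[eid] = v
        return out

    def to_fasta(self) -> str:
        buf = io.StringIO()
        for v in self.variants:
            buf.write(f">{v.accession}\n")
            _write_wrapped(buf, v.sequence)
        for header, seq in self.reference_records:
            buf.write(f">{header}\n")
            _write_wrapped(buf, seq)
        return buf.getvalue()

    def write_fasta(self, path: str | Path) -> None:
        Path(path).write_text(self.to_fasta())


def _write_wrapped(buf: io.StringIO, seq: str, width: int = 60) -> None:
    seq = seq.upper()
    for i in range(0, len(seq), width):
        buf.write(seq[i : i + width] + "\n")


def read_reference_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def build_database(
    transcripts: Mapping[str, Transcript],
    events: Sequence[Event],
    reference_proteome: Iterable[tuple[str, str]],
    min_support: int = 2,
    allow_open_ended: bool = False,
    codes: Mapping[str, str] = DEFAULT_EVENT_CODES,
) -> VariantDatabase:
    """Predict, filter, de-duplicate and tag variant proteins, then append
    the reference proteome records verbatim.

    Events below ``min_support`` are excluded.  Exact duplicate variant
    sequences collapse to one record (the lexicographically first event id
    wins; all merged ids are retained in the report and on the record).
    Output ordering is deterministic: variants sorted by event id, then
    reference records in input order.
    """
    report = BuildReport(n_events=len(events))

    unknown = sorted({e.transcript_id for e in events} - set(transcripts))
    if unknown:
        raise ValueError(f"events reference unknown transcripts: {', '.join(unknown)}")
    ids = [e.event_id for e in events]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate event ids: {', '.join(dupes)}")

    predicted: list[VariantProtein] = []
    for e in sorted(events, key=lambda e: e.event_id):
        if e.support_count < min_support:
            report.n_below_support += 1
            continue
        v = predict_variant_protein(
            transcripts[e.transcript_id], e, allow_open_ended=allow_open_ended, codes=codes
        )
        if v is None:
            # distinguish "no ORF" from "identical product" for the report
            t = transcripts[e.transcript_id]
            vt = apply_combined(t, e) if isinstance(e, CombinedEvent) else apply_event(t, e)
            if largest_orf(vt.sequence, allow_open_ended=allow_open_ended) is None:
                report.n_no_orf += 1
            else:
                report.n_identical += 1
            continue
        report.n_kept += 1
        predicted.append(v)

    by_seq: dict[str, VariantProtein] = {}
    for v in predicted:  # already sorted by event id
        if v.sequence in by_seq:
            kept = by_seq[v.sequence]
            merged = kept.merged_event_ids + (v.event_ref,)
            by_seq[v.sequence] = VariantProtein(
                **{**kept.__dict__, "merged_event_ids": merged}
            )
            report.n_deduped += 1
            report.merged[kept.event_ref] = merged
        else:
            by_seq[v.sequence] = v

    variants = sorted(by_seq.values(), key=lambda v: v.event_ref)
    reference_records = list(reference_proteome)
    report.n_reference_records = len(reference_records)
    ref_seqs = {seq for _, seq in reference_records}
    report.reference_collisions = sorted(
        v.accession for v in variants if v.sequence in ref_seqs
    )

    return VariantDatabase(
        variants=variants,
        reference_records=reference_records,
        report=report,
        events={e.event_id: e for e in events},
    )
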