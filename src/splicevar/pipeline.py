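"""ASE-supporting peptide calling, TIS classification and reporting.

The pipeline consumes a search-engine peptide table (MaxQuant
``peptides.txt`` dialect, or any TSV with a ``Sequence`` column), removes
reverse/contaminant rows, and keeps a peptide as *ASE-supporting* when

1. its protein assignments contain only variant-tagged accessions (no
   reference hit) — recomputed from the database when assignments are
   absent; and
2. it is absent from the reference tryptic-peptide universe.

Supporting peptides are grouped per event.  An event whose support
includes an N-terminal peptide of a variant that initiates away from the
reference start is an alternative-TIS event, classified into:

``A_downstream``
    the variant initiates downstream of (or in place of a deleted)
    reference start and its variant-specific N-terminus lies clear of the
    modified region;
``B_downstream_start_affected``
    as A, but the modified region overlaps the variant-specific
    N-terminus (the protein's beginning is directly shaped by the event);
``C_upstream``
    the variant initiates upstream of the still-present reference start.

Two extra flags are computed per TIS event: whether the chosen ATG is the
first one downstream of the event, and whether the isoform pair fits the
amino-terminus-only difference model (frame-preserving event, no
introduced in-frame stop, identical sequence from the first residue
downstream of the modification to the C-terminus).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import global_align
from .database import VariantDatabase, VariantProtein, event_type_code
from .digest import DigestParams, PeptideIndex, TrypticPeptide, digest
from .model import PipelineConfig, decode_header
from .orf import STOP_CODONS

logger = logging.getLogger(__name__)

__all__ = [
    "IdentifiedPeptide",
    "SupportingPeptide",
    "ASERecord",
    "TisClassification",
    "MergeSummary",
    "FrequencyTable",
    "parse_identifications",
    "detect_nterminal",
    "classify_tis",
    "call_ase_support",
    "merge_result_sets",
    "event_frequency_table",
    "render_alignment_report",
    "write_ase_table",
    "read_ase_table",
]


# ---------------------------------------------------------------------------
# Identification tables


@dataclass(frozen=True)
class IdentifiedPeptide:
    sequence: str
    accessions: tuple[str, ...] = ()
    score: float | None = None
    intensity: float | None = None
    reverse_flag: bool = False
    contaminant_flag: bool = False
    source_engine: str = "probabilistic"


def parse_identifications(
    table: str | Path | pd.DataFrame, source_engine: str = "probabilistic"
) -> list[IdentifiedPeptide]:
    """Parse a peptide identification table, dropping reverse and
    contaminant rows.

    Recognizes the MaxQuant ``peptides.txt`` columns ``Sequence``,
    ``Proteins``, ``Score``, ``Intensity``, ``Reverse`` and ``Potential
    contaminant`` (``+`` flags); any TSV with at least a ``Sequence``
    column is accepted, with absent metadata left unset.
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    if "Sequence" not in df.columns:
        raise ValueError("identification table lacks a 'Sequence' column")

    def flag(row, col: str) -> bool:
        return col in df.columns and str(row[col]).strip() == "+"

    def number(row, col: str) -> float | None:
        if col not in df.columns:
            return None
        text = str(row[col]).strip()
        if not text:
            return None
        try:
            return float(text)
        except ValueError:
            return None

    peptides: list[IdentifiedPeptide] = []
    n_removed = 0
    for _, row in df.iterrows():
        if flag(row, "Reverse") or flag(row, "Potential contaminant"):
            n_removed += 1
            continue
        accessions = ()
        if "Proteins" in df.columns and str(row["Proteins"]).strip():
            accessions = tuple(
                a.strip() for a in str(row["Proteins"]).split(";") if a.strip()
            )
        peptides.append(
            IdentifiedPeptide(
                sequence=str(row["Sequence"]).strip().upper(),
                accessions=accessions,
                score=number(row, "Score"),
                intensity=number(row, "Intensity"),
                source_engine=source_engine,
            )
        )
    logger.info("parse_identifications: kept %d peptides, removed %d flagged rows",
                len(peptides), n_removed)
    return peptides


# ---------------------------------------------------------------------------
# TIS classification


@dataclass(frozen=True)
class TisClassification:
    category: str | None  # A_downstream / B_downstream_start_affected / C_upstream
    first_atg_downstream: bool | None
    wilson_model: bool | None
    orf_disrupting: bool | None


def detect_nterminal(
    p: TrypticPeptide, v: VariantProtein, nterm_met_cleavage: bool = True
) -> bool:
    """True when a peptide matches the protein's beginning: residue 1, or
    residue 2 of a Met-initiated protein when initiator-Met cleavage is
    considered."""
    if p.start_pos == 1:
        return True
    return (
        p.start_pos == 2
        and nterm_met_cleavage
        and v.sequence.startswith("M")
    )


def _common_suffix_len(a: str, b: str) -> int:
    n = 0
    while n < len(a) and n < len(b) and a[-1 - n] == b[-1 - n]:
        n += 1
    return n


def classify_tis(v: VariantProtein, first_atg_in_frame: bool = False) -> TisClassification:
    """Classify an alternative-TIS variant into categories A/B/C and
    compute the first-ATG and amino-terminus-model flags.

    Returns all-``None`` when the variant actually initiates at the mapped
    reference start (no alternative TIS).
    """
    r = v.coord_map[v.reference_cds_start]
    s = v.tis_mrna_offset
    regions = v.modified_regions
    if r is not None and s == r:
        return TisClassification(None, None, None, None)

    # --- category ---------------------------------------------------------
    if r is not None and s < r:
        category = "C_upstream"
    else:
        suffix = _common_suffix_len(v.sequence, v.reference_protein)
        k = len(v.sequence) - suffix  # variant-specific N-terminal residues
        span_end = s + 3 * max(k, 1)  # the start codon itself always counts
        affected = False
        for a, b in regions:
            if a == b:
                # zero-length junction: counts when a codon of the span crosses it
                if s < a < span_end:
                    affected = True
            elif a < span_end and b > s:
                affected = True
        category = "B_downstream_start_affected" if affected else "A_downstream"

    # --- first ATG downstream of the event --------------------------------
    boundary = max((b for _, b in regions), default=0)
    first_atg = None
    pos = v.mrna.find("ATG", boundary)
    while pos != -1:
        if not first_atg_in_frame or (pos - s) % 3 == 0:
            first_atg = pos
            break
        pos = v.mrna.find("ATG", pos + 1)
    first_atg_downstream = first_atg is not None and first_atg == s

    # --- amino-terminus-only difference (frame-preserving) model ----------
    cds_end = min(
        v.reference_cds_start + 3 * (len(v.reference_protein) + 1), len(v.coord_map)
    )
    deletions = sum(
        1
        for p in range(v.reference_cds_start, cds_end)
        if v.coord_map[p] is None
    )
    # inverse lookup for insertion anchoring: variant position -> ref position
    mapped = [(vp, rp) for rp, vp in enumerate(v.coord_map) if vp is not None]
    insertions = 0
    for a, b in regions:
        if a == b:
            continue
        nxt = next((rp for vp, rp in mapped if vp >= b), None)
        if nxt is not None and v.reference_cds_start < nxt < cds_end:
            insertions += b - a
    frame_ok = (insertions - deletions) % 3 == 0

    m_end = max((b for _, b in regions), default=0)
    idx = max(0, math.ceil((m_end - s) / 3)) if m_end > s else 0
    tail = v.sequence[idx:]
    shared_start = s + 3 * idx
    introduced_stop = False
    if r is not None:
        p = r
        while p + 3 <= shared_start:
            if v.mrna[p : p + 3] in STOP_CODONS:
                introduced_stop = True
                break
            p += 3
    wilson = (
        frame_ok
        and bool(tail)
        and v.reference_protein.endswith(tail)
        and not introduced_stop
    )
    return TisClassification(
        category=category,
        first_atg_downstream=first_atg_downstream,
        wilson_model=wilson,
        orf_disrupting=not wilson,
    )


# ---------------------------------------------------------------------------
# ASE support calling


@dataclass(frozen=True)
class SupportingPeptide:
    sequence: str
    start_pos: int
    is_nterminal: bool
    shared_variant: bool = False
    score: float | None = None
    intensity: float | None = None


@dataclass(frozen=True)
class ASERecord:
    event_id: str
    event_type: str
    supporting_peptides: tuple[SupportingPeptide, ...]
    is_tis: bool
    tis_category: str | None = None
    first_atg_downstream: bool | None = None
    wilson_model: bool | None = None
    orf_disrupting: bool | None = None
    source_engines: tuple[str, ...] = ()

    @property
    def best_score(self) -> float | None:
        scores = [p.score for p in self.supporting_peptides if p.score is not None]
        return max(scores) if scores else None

    @property
    def max_intensity(self) -> float | None:
        vals = [p.intensity for p in self.supporting_peptides if p.intensity is not None]
        return max(vals) if vals else None


def _alternative_tis(v: VariantProtein) -> bool:
    r = v.coord_map[v.reference_cds_start]
    return r is None or v.tis_mrna_offset != r


def call_ase_support(
    peptides: Sequence[IdentifiedPeptide],
    db: VariantDatabase,
    reference_index: PeptideIndex,
    config: PipelineConfig | None = None,
) -> tuple[list[ASERecord], list[str]]:
    """Two-stage ASE-support calling plus TIS classification.

    Stage 1 rejects any peptide whose protein assignments include a
    non-variant accession (assignment evidence outranks recomputation);
    when assignments are absent the stage is recomputed by locating the
    peptide in the database.  Stage 2 rejects peptides present in the
    reference tryptic universe (optionally also substrings of the
    template).  Peptides mapping to no database entry are returned as
    warnings, not errors.
    """
    config = config or PipelineConfig()
    params = reference_index.params
    by_accession = db.variant_by_accession()
    digest_cache: dict[str, set[str]] = {}

    def variant_peptide_set(v: VariantProtein) -> set[str]:
        if v.accession not in digest_cache:
            digest_cache[v.accession] = {
                p.sequence
                for p in digest(
                    v.sequence,
                    max_missed=params.max_missed,
                    min_length=params.min_length,
                    met_removed=params.met_removed,
                )
            }
        return digest_cache[v.accession]

    warnings: list[str] = []
    support: dict[str, list[tuple[SupportingPeptide, str]]] = {}
    event_variant: dict[str, VariantProtein] = db.variant_by_event()

    for pep in peptides:
        if pep.reverse_flag or pep.contaminant_flag:
            continue
        matched: list[VariantProtein] = []
        if pep.accessions:
            stage1_reject = False
            for acc in pep.accessions:
                try:
                    decoded = decode_header(acc)
                except ValueError:
                    warnings.append(f"unparsable accession {acc!r} for {pep.sequence}")
                    continue
                if not decoded.is_variant:
                    stage1_reject = True  # seen on a reference entry
                    break
                v = by_accession.get(decoded.accession)
                if v is None:
                    warnings.append(f"accession {acc!r} not in database ({pep.sequence})")
                else:
                    matched.append(v)
            if stage1_reject:
                continue
        else:
            if pep.sequence in reference_index:
                continue
            matched = [
                v for v in db.variants if pep.sequence in variant_peptide_set(v)
            ]
        if pep.sequence in reference_index:  # stage 2
            continue
        if config.template_substring:
            matched = [v for v in matched if pep.sequence not in v.reference_protein]
        if not matched:
            warnings.append(f"peptide {pep.sequence} maps to no database entry")
            continue

        events_hit = {eid for v in matched for eid in v.merged_event_ids}
        shared = len(events_hit) > 1
        for v in matched:
            start = v.sequence.find(pep.sequence)
            if start == -1:
                warnings.append(
                    f"peptide {pep.sequence} not located in {v.accession}"
                )
                continue
            start_pos = start + 1
            nterm = start_pos == 1 or (
                start_pos == 2 and config.nterm_met_cleavage and v.sequence.startswith("M")
            )
            sp = SupportingPeptide(
                sequence=pep.sequence,
                start_pos=start_pos,
                is_nterminal=nterm,
                shared_variant=shared,
                score=pep.score,
                intensity=pep.intensity,
            )
            for eid in v.merged_event_ids:
                support.setdefault(eid, []).append((sp, pep.source_engine))

    records: list[ASERecord] = []
    for eid in sorted(support):
        entries = support[eid]
        # de-duplicate peptides per event, keeping the best-scoring row
        by_seq: dict[str, SupportingPeptide] = {}
        engines: set[str] = set()
        for sp, engine in entries:
            engines.add(engine)
            prev = by_seq.get(sp.sequence)
            if prev is None or (sp.score or 0) > (prev.score or 0):
                by_seq[sp.sequence] = sp
        peps = tuple(sorted(by_seq.values(), key=lambda p: (p.start_pos, p.sequence)))
        v = event_variant[eid]
        etype = (
            event_type_code(db.events[eid], config.event_codes)
            if eid in db.events
            else v.event_type_code
        )
        is_tis = any(p.is_nterminal for p in peps) and _alternative_tis(v)
        cls = (
            classify_tis(v, first_atg_in_frame=config.first_atg_in_frame)
            if is_tis
            else TisClassification(None, None, None, None)
        )
        records.append(
            ASERecord(
                event_id=eid,
                event_type=etype,
                supporting_peptides=peps,
                is_tis=is_tis,
                tis_category=cls.category,
                first_atg_downstream=cls.first_atg_downstream,
                wilson_model=cls.wilson_model,
                orf_disrupting=cls.orf_disrupting,
                source_engines=tuple(sorted(engines)),
            )
        )
    return records, warnings


# ---------------------------------------------------------------------------
# Merging and frequency tables


@dataclass(frozen=True)
class MergeSummary:
    n_a: int
    n_b: int
    n_overlap: int

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_overlap


def merge_result_sets(
    a: Sequence[ASERecord], b: Sequence[ASERecord]
) -> tuple[list[ASERecord], MergeSummary]:
    """Union two result sets by event id; supporting peptides and source
    engines are pooled.  Conflicting event types for one id are an error."""
    merged: dict[str, ASERecord] = {r.event_id: r for r in a}
    overlap = 0
    for rec in b:
        prev = merged.get(rec.event_id)
        if prev is None:
            merged[rec.event_id] = rec
            continue
        overlap += 1
        if prev.event_type != rec.event_type:
            raise ValueError(
                f"conflicting event_type for {rec.event_id}: "
                f"{prev.event_type} vs {rec.event_type}"
            )
        by_seq: dict[str, SupportingPeptide] = {p.sequence: p for p in prev.supporting_peptides}
        for p in rec.supporting_peptides:
            if p.sequence not in by_seq or (p.score or 0) > (by_seq[p.sequence].score or 0):
                by_seq[p.sequence] = p
        peps = tuple(sorted(by_seq.values(), key=lambda p: (p.start_pos, p.sequence)))
        merged[rec.event_id] = replace(
            prev,
            supporting_peptides=peps,
            is_tis=prev.is_tis or rec.is_tis,
            tis_category=prev.tis_category or rec.tis_category,
            first_atg_downstream=(
                prev.first_atg_downstream
                if prev.first_atg_downstream is not None
                else rec.first_atg_downstream
            ),
            wilson_model=prev.wilson_model if prev.wilson_model is not None else rec.wilson_model,
            orf_disrupting=(
                prev.orf_disrupting if prev.orf_disrupting is not None else rec.orf_disrupting
            ),
            source_engines=tuple(sorted(set(prev.source_engines) | set(rec.source_engines))),
        )
    summary = MergeSummary(n_a=len(a), n_b=len(b), n_overlap=overlap)
    out = sorted(merged.values(), key=lambda r: r.event_id)
    return out, summary


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class FrequencyTable:
    simple_counts: Mapping[str, int]
    simple_percents: Mapping[str, int]
    n_simple: int
    n_complex: int

    def to_tsv(self) -> str:
        lines = ["event_type\tcount\tpercent"]
        for code in sorted(self.simple_counts):
            lines.append(
                f"{code}\t{self.simple_counts[code]}\t{self.simple_percents[code]}"
            )
        lines.append(f"simple_total\t{self.n_simple}\t")
        lines.append(f"complex_total\t{self.n_complex}\t")
        return "\n".join(lines) + "\n"


def event_frequency_table(records: Sequence[ASERecord]) -> FrequencyTable:
    """Per-type counts among simple events with integer percentages
    (round half up); combined events are counted separately as complex."""
    simple: dict[str, int] = {}
    n_complex = 0
    for rec in records:
        if rec.event_type.startswith("CASE"):
            n_complex += 1
        else:
            simple[rec.event_type] = simple.get(rec.event_type, 0) + 1
    n_simple = sum(simple.values())
    percents = {
        code: _round_half_up(100.0 * count / n_simple) if n_simple else 0
        for code, count in simple.items()
    }
    return FrequencyTable(
        simple_counts=simple,
        simple_percents=percents,
        n_simple=n_simple,
        n_complex=n_complex,
    )


# ---------------------------------------------------------------------------
# Alignment reports


def _peptide_mask(protein: str, peptides: Iterable[str]) -> list[bool]:
    mask = [False] * len(protein)
    for pep in peptides:
        pos = protein.find(pep)
        if pos == -1:
            raise ValueError(f"peptide {pep!r} not found in its sequence")
        while pos != -1:
            for k in range(pos, pos + len(pep)):
                mask[k] = True
            pos = protein.find(pep, pos + 1)
    return mask


def render_alignment_report(
    v: VariantProtein,
    shared_peptides: Sequence[str] = (),
    variant_peptides: Sequence[str] = (),
    html: bool = False,
    width: int = 60,
) -> str:
    """Render the reference-vs-variant global alignment in fixed-width
    blocks, marking reference-supported peptides on the reference row
    (``=``) and variant-specific peptides on the variant row (``*``).
    The HTML emitter wraps the same layout in ``<pre>`` with highlight
    spans.  Output is byte-stable for identical inputs."""
    ref = v.reference_protein
    var = v.sequence
    aln = global_align(ref, var)
    ref_mask = _peptide_mask(ref, shared_peptides)
    var_mask = _peptide_mask(var, variant_peptides)

    cols = len(aln.aligned_a)
    ref_marks = []
    var_marks = []
    match_line = []
    ri = vi = 0
    for c in range(cols):
        ra, vb = aln.aligned_a[c], aln.aligned_b[c]
        ref_marks.append("=" if ra != "-" and ref_mask[ri] else " ")
        var_marks.append("*" if vb != "-" and var_mask[vi] else " ")
        if ra == "-" or vb == "-":
            match_line.append(" ")
        else:
            match_line.append("|" if ra == vb else ".")
        if ra != "-":
            ri += 1
        if vb != "-":
            vi += 1

    header = [
        f"# {v.accession}",
        f"# template {v.tag.refseq_name}  event {v.event_ref} ({v.event_type_code})",
        f"# identity {100.0 * aln.identity:.1f}% over {cols} aligned columns",
        "# '=' reference-supported peptide, '*' variant-specific peptide",
    ]
    blocks: list[str] = []
    ra_pos = rb_pos = 0
    for start in range(0, cols, width):
        end = min(start + width, cols)
        a_chunk = aln.aligned_a[start:end]
        b_chunk = aln.aligned_b[start:end]
        a_n = sum(ch != "-" for ch in a_chunk)
        b_n = sum(ch != "-" for ch in b_chunk)
        lines = []
        marks = "".join(ref_marks[start:end]).rstrip()
        if marks:
            lines.append(f"{'':>4} {'':>5} {marks}")
        lines.append(f"REF  {ra_pos + 1 if a_n else ra_pos:>5} {a_chunk} {ra_pos + a_n}")
        lines.append(f"{'':>4} {'':>5} {''.join(match_line[start:end])}")
        lines.append(f"VAR  {rb_pos + 1 if b_n else rb_pos:>5} {b_chunk} {rb_pos + b_n}")
        marks = "".join(var_marks[start:end]).rstrip()
        if marks:
            lines.append(f"{'':>4} {'':>5} {marks}")
        blocks.append("\n".join(lines))
        ra_pos += a_n
        rb_pos += b_n
    text = "\n".join(header) + "\n\n" + "\n\n".join(blocks) + "\n"
    if not html:
        return text
    return _render_html(v, aln, ref_marks, var_marks, match_line, width)


def _render_html(v, aln, ref_marks, var_marks, match_line, width: int) -> str:
    def span_row(aligned: str, marks: list[str], css: str, start: int, end: int) -> str:
        out = []
        open_span = False
        for c in range(start, end):
            marked = marks[c] != " "
            if marked and not open_span:
                out.append(f'<span class="{css}">')
                open_span = True
            if not marked and open_span:
                out.append("</span>")
                open_span = False
            out.append(aligned[c])
        if open_span:
            out.append("</span>")
        return "".join(out)

    cols = len(aln.aligned_a)
    blocks = []
    for start in range(0, cols, width):
        end = min(start + width, cols)
        blocks.append(
            "REF  " + span_row(aln.aligned_a, ref_marks, "shared-peptide", start, end)
            + "\n     " + "".join(match_line[start:end])
            + "\nVAR  " + span_row(aln.aligned_b, var_marks, "variant-peptide", start, end)
        )
    style = (
        "<style>.shared-peptide{background:#f90}.variant-peptide{background:#ff0}</style>"
    )
    body = "\n\n".join(blocks)
    return (
        f"<html><head>{style}</head><body><h3>{v.accession}</h3>"
        f"<p>identity {100.0 * aln.identity:.1f}%</p><pre>{body}</pre></body></html>\n"
    )


# ---------------------------------------------------------------------------
# ASE result TSV


_ASE_COLUMNS = [
    "event_id",
    "event_type",
    "n_peptides",
    "peptides",
    "is_tis",
    "tis_category",
    "first_atg_downstream",
    "wilson_model",
    "orf_disrupting",
    "source_engines",
    "best_score",
    "max_intensity",
]


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def write_ase_table(records: Sequence[ASERecord], path: str | Path) -> None:
    lines = ["\t".join(_ASE_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.event_id,
                    r.event_type,
                    str(len(r.supporting_peptides)),
                    ";".join(p.sequence for p in r.supporting_peptides),
                    _cell(r.is_tis),
                    _cell(r.tis_category),
                    _cell(r.first_atg_downstream),
                    _cell(r.wilson_model),
                    _cell(r.orf_disrupting),
                    ";".join(r.source_engines),
                    _cell(r.best_score),
                    _cell(r.max_intensity),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_bool(text: str) -> bool | None:
    return None if text == "" else text == "true"


def read_ase_table(path: str | Path) -> list[ASERecord]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _ASE_COLUMNS:
        raise ValueError(f"{path}: not an ASE result table")
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        row = dict(zip(_ASE_COLUMNS, f))
        peps = tuple(
            SupportingPeptide(sequence=s, start_pos=0, is_nterminal=False)
            for s in row["peptides"].split(";")
            if s
        )
        records.append(
            ASERecord(
                event_id=row["event_id"],
                event_type=row["event_type"],
                supporting_peptides=peps,
                is_tis=row["is_tis"] == "true",
                tis_category=row["tis_category"] or None,
                first_atg_downstream=_parse_bool(row["first_atg_downstream"]),
                wilson_model=_parse_bool(row["wilson_model"]),
                orf_disrupting=_parse_bool(row["orf_disrupting"]),
                source_engines=tuple(
                    e for e in row["source_engines"].split(";") if e
                ),
            )
        )
    return records
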