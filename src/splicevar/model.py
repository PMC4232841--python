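"""Domain model: transcripts, splice-event taxonomy, and the variant header codec.

A :class:`Transcript` is a sequence-backed gene model: ordered exon and
intron sequences in transcript orientation (5'→3') plus the annotated CDS
start (and optionally end) in spliced-mRNA coordinates.  Splice events are
typed edits of that block structure:

``EXON_SKIP``
    remove a contiguous run of exons.
``ALT_3SS``
    shift an exon's acceptor: negative shift extends the exon into the
    upstream intron, positive shift truncates the exon 5' end.
``ALT_5SS``
    shift an exon's donor: positive shift extends into the downstream
    intron, negative shift truncates the exon 3' end.
``INTRON_RETAIN``
    keep an intron in the mature mRNA.
``DUAL_SPECIFIC``
    taxonomy label only; such events are never generated or applied.

Variant protein records are tagged ``NAME# (TYPE:ID)`` so that downstream
peptide tables can be partitioned into variant and reference hits by header
alone; :func:`encode_header` / :func:`decode_header` are the codec.

All coordinates are 0-based half-open in spliced-mRNA space; exon and
intron indices are 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import yaml

NUCLEOTIDES = frozenset("ACGTN")

__all__ = [
    "EventType",
    "Transcript",
    "SpliceEvent",
    "CombinedEvent",
    "HeaderTag",
    "DecodedHeader",
    "PipelineConfig",
    "HeaderParseError",
    "encode_header",
    "decode_header",
    "validate_event",
    "read_event_table",
    "write_event_table",
    "read_transcripts",
    "write_transcripts",
    "transcripts_from_gtf",
    "DEFAULT_EVENT_CODES",
]


class EventType(str, Enum):
    EXON_SKIP = "EXON_SKIP"
    ALT_3SS = "ALT_3SS"
    ALT_5SS = "ALT_5SS"
    INTRON_RETAIN = "INTRON_RETAIN"
    DUAL_SPECIFIC = "DUAL_SPECIFIC"


#: Short codes used in FASTA header tags and report tables.
DEFAULT_EVENT_CODES: Mapping[str, str] = {
    EventType.EXON_SKIP.value: "ES",
    EventType.ALT_3SS.value: "A3SS",
    EventType.ALT_5SS.value: "A5SS",
    EventType.INTRON_RETAIN.value: "IR",
    EventType.DUAL_SPECIFIC.value: "DS",
    "COMBINED": "CASE",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs shared across the pipeline stages.

    Defaults mirror the study conditions: events need support from at
    least two expressed sequences, tryptic digestion allows two missed
    cleavages and a 7-residue minimum, and ORFs must be stop-terminated.
    """

    event_codes: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_EVENT_CODES))
    min_support: int = 2
    allow_open_ended: bool = False
    max_missed: int = 2
    min_length: int = 7
    il_equivalence: bool = False
    nterm_met_cleavage: bool = True
    first_atg_in_frame: bool = False
    template_substring: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        codes = dict(DEFAULT_EVENT_CODES)
        codes.update(data.pop("event_codes", {}))
        return cls(event_codes=codes, **data)


# ---------------------------------------------------------------------------
# Transcript


@dataclass(frozen=True)
class Transcript:
    """Sequence-backed transcript model.

    ``introns`` has exactly one entry fewer than ``exons``; ``cds_start``
    (and optional ``cds_end``) index into the spliced mRNA, which is the
    concatenation of the exon sequences.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[str, ...]
    introns: tuple[str, ...]
    cds_start: int
    cds_end: int | None = None

    def __post_init__(self) -> None:
        exons = tuple(e.upper() for e in self.exons)
        introns = tuple(i.upper() for i in self.introns)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "introns", introns)
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript needs at least one exon")
        if len(introns) != len(exons) - 1:
            raise ValueError(
                f"{self.transcript_id}: expected {len(exons) - 1} introns, got {len(introns)}"
            )
        for kind, seqs in (("exon", exons), ("intron", introns)):
            for i, s in enumerate(seqs):
                if not s:
                    raise ValueError(f"{self.transcript_id}: empty {kind} {i}")
                bad = set(s) - NUCLEOTIDES
                if bad:
                    raise ValueError(
                        f"{self.transcript_id}: {kind} {i} has non-ACGTN characters {sorted(bad)}"
                    )
        length = sum(len(e) for e in exons)
        if not 0 <= self.cds_start < length:
            raise ValueError(f"{self.transcript_id}: cds_start {self.cds_start} outside mRNA")
        if self.cds_end is not None:
            if not self.cds_start < self.cds_end <= length:
                raise ValueError(f"{self.transcript_id}: invalid cds_end {self.cds_end}")
            if (self.cds_end - self.cds_start) % 3:
                raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def mrna(self) -> str:
        """Reference spliced mRNA (exon concatenation)."""
        return "".join(self.exons)

    @property
    def exon_offsets(self) -> tuple[int, ...]:
        """Start offset of each exon in the spliced mRNA."""
        offsets = []
        pos = 0
        for e in self.exons:
            offsets.append(pos)
            pos += len(e)
        return tuple(offsets)


# ---------------------------------------------------------------------------
# Events


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing modification of a transcript.

    ``params`` keys depend on ``event_type``: ``skip=(i, j)`` for
    EXON_SKIP, ``exon``/``shift`` for the splice-site classes, ``intron``
    for INTRON_RETAIN.
    """

    event_id: str
    transcript_id: str
    event_type: EventType
    params: Mapping[str, object]
    support_count: int = 2

    def __post_init__(self) -> None:
        if self.support_count < 1:
            raise ValueError(f"{self.event_id}: support_count must be >= 1")
        object.__setattr__(self, "event_type", EventType(self.event_type))
        object.__setattr__(self, "params", dict(self.params))

    @property
    def skip_range(self) -> tuple[int, int]:
        i, j = self.params["skip"]  # type: ignore[index]
        return int(i), int(j)

    @property
    def exon(self) -> int:
        return int(self.params["exon"])  # type: ignore[arg-type]

    @property
    def shift(self) -> int:
        return int(self.params["shift"])  # type: ignore[arg-type]

    @property
    def intron(self) -> int:
        return int(self.params["intron"])  # type: ignore[arg-type]


@dataclass(frozen=True)
class CombinedEvent:
    """Two or more non-overlapping splice events applied jointly (a CASE)."""

    event_id: str
    transcript_id: str
    events: tuple[SpliceEvent, ...]
    support_count: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.support_count < 1:
            raise ValueError(f"{self.event_id}: support_count must be >= 1")


Event = Union[SpliceEvent, CombinedEvent]


def _claims(e: SpliceEvent) -> set[tuple[str, int]]:
    """Block-structure resources an event modifies, used for the CASE
    non-overlap check.  Truncation-only shifts do not claim the intron, so
    opposite-side truncations around one intron may co-occur."""
    t = e.event_type
    if t is EventType.EXON_SKIP:
        i, j = e.skip_range
        claims: set[tuple[str, int]] = set()
        for x in range(i, j + 1):
            claims |= {("exon", x), ("acceptor", x), ("donor", x)}
        for x in range(i, j):
            claims.add(("intron", x))
        return claims
    if t is EventType.ALT_3SS:
        claims = {("acceptor", e.exon)}
        if e.shift < 0:
            claims.add(("intron", e.exon - 1))
        return claims
    if t is EventType.ALT_5SS:
        claims = {("donor", e.exon)}
        if e.shift > 0:
            claims.add(("intron", e.exon))
        return claims
    if t is EventType.INTRON_RETAIN:
        return {("intron", e.intron)}
    return {("event", -1)}


def _anchor(e: SpliceEvent) -> int:
    """Sort key used to check the 5'→3' ordering of CASE constituents."""
    if e.event_type is EventType.EXON_SKIP:
        return 2 * e.skip_range[0]
    if e.event_type in (EventType.ALT_3SS, EventType.ALT_5SS):
        return 2 * e.exon + (1 if e.event_type is EventType.ALT_5SS else 0)
    return 2 * e.intron + 1


def validate_event(t: Transcript, e: Event) -> list[str]:
    """Check an event against a transcript; returns human-readable
    violations (empty list means valid).  Never raises on well-typed input.
    """
    violations: list[str] = []
    if isinstance(e, CombinedEvent):
        if len(e.events) < 2:
            violations.append(f"{e.event_id}: combined event needs >= 2 constituents")
        seen: dict[tuple[str, int], str] = {}
        anchors = []
        for sub in e.events:
            if sub.transcript_id != e.transcript_id:
                violations.append(
                    f"{sub.event_id}: constituent transcript {sub.transcript_id} "
                    f"differs from {e.transcript_id}"
                )
            violations.extend(validate_event(t, sub))
            for claim in _claims(sub):
                if claim in seen:
                    violations.append(
                        f"overlap: {seen[claim]} and {sub.event_id} both modify "
                        f"{claim[0]} {claim[1]}"
                    )
                else:
                    seen[claim] = sub.event_id
            anchors.append(_anchor(sub))
        if anchors != sorted(anchors):
            violations.append(f"{e.event_id}: constituents not ordered 5'->3'")
        return violations

    n = len(t.exons)
    try:
        if e.event_type is EventType.EXON_SKIP:
            i, j = e.skip_range
            if not (0 <= i <= j < n):
                violations.append(f"{e.event_id}: skip range [{i},{j}] outside 0..{n - 1}")
        elif e.event_type is EventType.ALT_3SS:
            i, s = e.exon, e.shift
            if not 0 <= i < n:
                violations.append(f"{e.event_id}: exon index {i} outside 0..{n - 1}")
            elif i == 0:
                violations.append(f"{e.event_id}: ALT_3SS not applicable to exon 0")
            elif s == 0:
                violations.append(f"{e.event_id}: zero acceptor shift")
            elif s < 0 and -s > len(t.introns[i - 1]):
                violations.append(
                    f"{e.event_id}: acceptor extension {-s} exceeds intron {i - 1} "
                    f"length {len(t.introns[i - 1])}"
                )
            elif s > 0 and s >= len(t.exons[i]):
                violations.append(
                    f"{e.event_id}: acceptor truncation {s} >= exon {i} length {len(t.exons[i])}"
                )
        elif e.event_type is EventType.ALT_5SS:
            i, s = e.exon, e.shift
            if not 0 <= i < n:
                violations.append(f"{e.event_id}: exon index {i} outside 0..{n - 1}")
            elif i == n - 1:
                violations.append(f"{e.event_id}: ALT_5SS not applicable to last exon")
            elif s == 0:
                violations.append(f"{e.event_id}: zero donor shift")
            elif s > 0 and s > len(t.introns[i]):
                violations.append(
                    f"{e.event_id}: donor extension {s} exceeds intron {i} "
                    f"length {len(t.introns[i])}"
                )
            elif s < 0 and -s >= len(t.exons[i]):
                violations.append(
                    f"{e.event_id}: donor truncation {-s} >= exon {i} length {len(t.exons[i])}"
                )
        elif e.event_type is EventType.INTRON_RETAIN:
            k = e.intron
            if not 0 <= k < len(t.introns):
                violations.append(
                    f"{e.event_id}: intron index {k} outside 0..{len(t.introns) - 1}"
                )
        elif e.event_type is EventType.DUAL_SPECIFIC:
            violations.append(f"{e.event_id}: DUAL_SPECIFIC events cannot be applied")
    except (KeyError, TypeError, ValueError) as exc:
        violations.append(f"{e.event_id}: malformed params ({exc})")
    return violations


# ---------------------------------------------------------------------------
# Header codec

_DELIMS = "#():"
_VARIANT_RE = re.compile(
    r"^(?P<name>[^#()\s:][^#():]*)#\s*\((?P<etype>[^#():]+):(?P<sid>[^#():]+)\)\s*$"
)


class HeaderParseError(ValueError):
    def __init__(self, header: str, offset: int, message: str):
        self.header = header
        self.offset = offset
        super().__init__(f"{message} at offset {offset}: {header!r}")


@dataclass(frozen=True)
class HeaderTag:
    """The ``NAME# (TYPE:ID)`` provenance tag carried by variant records."""

    refseq_name: str
    event_type_code: str
    splooce_id: str

    def __post_init__(self) -> None:
        for fname in ("refseq_name", "event_type_code", "splooce_id"):
            value = getattr(self, fname)
            if not value:
                raise ValueError(f"header tag field {fname} is empty")
            bad = set(value) & set(_DELIMS)
            if bad:
                raise ValueError(
                    f"header tag field {fname} contains delimiter {sorted(bad)}: {value!r}"
                )


@dataclass(frozen=True)
class DecodedHeader:
    accession: str
    tag: HeaderTag | None = None

    @property
    def is_variant(self) -> bool:
        return self.tag is not None


def encode_header(tag: HeaderTag) -> str:
    """Render a tag as ``NAME# (TYPE:ID)`` (single canonical space)."""
    return f"{tag.refseq_name}# ({tag.event_type_code}:{tag.splooce_id})"


def decode_header(header: str) -> DecodedHeader:
    """Parse a FASTA description line.

    Variant-style headers yield their :class:`HeaderTag`; anything without
    the ``# (...)`` pattern is reported as a non-variant record whose
    accession is the first whitespace-delimited token.
    """
    text = header.lstrip(">").strip()
    if "#" not in text:
        accession = text.split()[0] if text.split() else ""
        return DecodedHeader(accession=accession)
    m = _VARIANT_RE.match(text)
    if m is None:
        raise HeaderParseError(header, text.index("#"), "malformed variant header")
    tag = HeaderTag(
        refseq_name=m.group("name").strip(),
        event_type_code=m.group("etype").strip(),
        splooce_id=m.group("sid").strip(),
    )
    return DecodedHeader(accession=encode_header(tag), tag=tag)


# ---------------------------------------------------------------------------
# Event TSV dialect
#
# Columns: event_id  transcript_id  event_type  params  support_count
# params examples: "skip=1-3", "exon=2;shift=+3", "intron=0".  Combined
# events use event_type=CASE and params
# "events=EXON_SKIP:skip=1-1|INTRON_RETAIN:intron=2".


def _params_to_str(e: SpliceEvent) -> str:
    t = e.event_type
    if t is EventType.EXON_SKIP:
        i, j = e.skip_range
        return f"skip={i}-{j}"
    if t in (EventType.ALT_3SS, EventType.ALT_5SS):
        return f"exon={e.exon};shift={e.shift:+d}"
    if t is EventType.INTRON_RETAIN:
        return f"intron={e.intron}"
    return ""


def _params_from_str(event_type: EventType, text: str, sep: str = ";") -> dict:
    kv = {}
    for part in filter(None, text.split(sep)):
        key, _, value = part.partition("=")
        kv[key.strip()] = value.strip()
    if event_type is EventType.EXON_SKIP:
        i, _, j = kv["skip"].partition("-")
        return {"skip": (int(i), int(j if j else i))}
    if event_type in (EventType.ALT_3SS, EventType.ALT_5SS):
        return {"exon": int(kv["exon"]), "shift": int(kv["shift"])}
    if event_type is EventType.INTRON_RETAIN:
        return {"intron": int(kv["intron"])}
    return {}


def write_event_table(events: Iterable[Event], path: str | Path) -> None:
    lines = ["event_id\ttranscript_id\tevent_type\tparams\tsupport_count"]
    for e in events:
        if isinstance(e, CombinedEvent):
            constituents = "|".join(
                f"{sub.event_type.value}:{_params_to_str(sub).replace(';', ',')}"
                for sub in e.events
            )
            lines.append(
                f"{e.event_id}\t{e.transcript_id}\tCASE\tevents={constituents}\t{e.support_count}"
            )
        else:
            lines.append(
                f"{e.event_id}\t{e.transcript_id}\t{e.event_type.value}\t"
                f"{_params_to_str(e)}\t{e.support_count}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_event_table(path: str | Path) -> list[Event]:
    events: list[Event] = []
    lines = Path(path).read_text().splitlines()
    header_seen = False
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if not line.lower().startswith("event_id"):
                raise ValueError(f"{path}: missing header line, got {line!r}")
            header_seen = True
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path}: expected 5 columns, got {len(fields)}: {line!r}")
        event_id, tid, etype, params, support = fields
        support_count = int(support)
        if etype == "CASE":
            body = params.partition("events=")[2]
            subs = []
            for k, chunk in enumerate(filter(None, body.split("|"))):
                sub_type_name, _, sub_params = chunk.partition(":")
                sub_type = EventType(sub_type_name)
                subs.append(
                    SpliceEvent(
                        event_id=f"{event_id}.{k}",
                        transcript_id=tid,
                        event_type=sub_type,
                        params=_params_from_str(sub_type, sub_params, sep=","),
                        support_count=support_count,
                    )
                )
            events.append(
                CombinedEvent(
                    event_id=event_id,
                    transcript_id=tid,
                    events=tuple(subs),
                    support_count=support_count,
                )
            )
        else:
            event_type = EventType(etype)
            events.append(
                SpliceEvent(
                    event_id=event_id,
                    transcript_id=tid,
                    event_type=event_type,
                    params=_params_from_str(event_type, params),
                    support_count=support_count,
                )
            )
    if not header_seen:
        raise ValueError(f"{path}: empty event table")
    return events


# ---------------------------------------------------------------------------
# Transcript ingestion: TSV + FASTA pair


def write_transcripts(transcripts: Iterable[Transcript], tsv: str | Path, fasta: str | Path) -> None:
    """Write the sequence-backed TSV/FASTA pair.

    The FASTA holds one record per block named ``{tid}|exon|{i}`` or
    ``{tid}|intron|{i}``; the TSV holds per-transcript metadata.
    """
    rows = ["transcript_id\tgene_id\tn_exons\tcds_start\tcds_end"]
    seqs: list[str] = []
    for t in transcripts:
        cds_end = "" if t.cds_end is None else str(t.cds_end)
        rows.append(f"{t.transcript_id}\t{t.gene_id}\t{len(t.exons)}\t{t.cds_start}\t{cds_end}")
        for i, e in enumerate(t.exons):
            seqs.append(f">{t.transcript_id}|exon|{i}\n{e}")
        for i, s in enumerate(t.introns):
            seqs.append(f">{t.transcript_id}|intron|{i}\n{s}")
    Path(tsv).write_text("\n".join(rows) + "\n")
    Path(fasta).write_text("\n".join(seqs) + "\n")


def read_transcripts(tsv: str | Path, fasta: str | Path) -> dict[str, Transcript]:
    from Bio import SeqIO

    blocks: dict[tuple[str, str, int], str] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        tid, kind, idx = rec.id.rsplit("|", 2)
        blocks[(tid, kind, int(idx))] = str(rec.seq).upper()

    transcripts: dict[str, Transcript] = {}
    lines = Path(tsv).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        tid, gene_id, n_exons, cds_start, cds_end = line.split("\t")
        n = int(n_exons)
        exons = tuple(blocks[(tid, "exon", i)] for i in range(n))
        introns = tuple(blocks[(tid, "intron", i)] for i in range(n - 1))
        transcripts[tid] = Transcript(
            transcript_id=tid,
            gene_id=gene_id,
            exons=exons,
            introns=introns,
            cds_start=int(cds_start),
            cds_end=int(cds_end) if cds_end else None,
        )
    return transcripts


# ---------------------------------------------------------------------------
# Transcript ingestion: GTF + genome FASTA


def transcripts_from_gtf(gtf_path: str | Path, genome_fasta: str | Path) -> dict[str, Transcript]:
    """Normalize GTF exon/CDS features plus a genome FASTA to sequence-backed
    transcripts.

    Minus-strand models are reverse-complemented so that exon/intron lists
    and CDS offsets are in transcript (5'→3') orientation.  The CDS is taken
    verbatim from the CDS features (include the stop codon in the CDS if a
    complete ``cds_end`` is wanted).
    """
    import gffutils
    from Bio import SeqIO
    from Bio.Seq import Seq

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    by_tid: dict[str, dict[str, list]] = {}
    for feature in db.all_features():
        if feature.featuretype not in ("exon", "CDS"):
            continue
        tid = feature.attributes["transcript_id"][0]
        info = by_tid.setdefault(tid, {"exon": [], "CDS": [], "meta": feature})
        info[feature.featuretype].append(feature)

    out: dict[str, Transcript] = {}
    for tid, info in sorted(by_tid.items()):
        exon_feats = sorted(info["exon"], key=lambda f: f.start)
        cds_feats = sorted(info["CDS"], key=lambda f: f.start)
        if not exon_feats or not cds_feats:
            raise ValueError(f"{tid}: needs both exon and CDS features")
        strand = exon_feats[0].strand
        chrom = exon_feats[0].seqid
        gene_id = exon_feats[0].attributes.get("gene_id", [tid])[0]
        contig = genome[chrom]

        def segment(start: int, end: int) -> str:
            seq = contig[start - 1 : end]  # GTF is 1-based inclusive
            return str(Seq(seq).reverse_complement()) if strand == "-" else seq

        exons = [segment(f.start, f.end) for f in exon_feats]
        introns = [
            segment(exon_feats[i].end + 1, exon_feats[i + 1].start - 1)
            for i in range(len(exon_feats) - 1)
        ]
        if strand == "-":
            exons.reverse()
            introns.reverse()
            exon_feats = exon_feats[::-1]

        # spliced-mRNA offset of a genomic position inside an exon
        def mrna_offset(genomic: int) -> int:
            pos = 0
            for f, seq in zip(exon_feats, exons):
                if f.start <= genomic <= f.end:
                    within = (f.end - genomic) if strand == "-" else (genomic - f.start)
                    return pos + within
                pos += len(seq)
            raise ValueError(f"{tid}: genomic position {genomic} not exonic")

        if strand == "-":
            cds_first = max(f.end for f in cds_feats)
            cds_last = min(f.start for f in cds_feats)
        else:
            cds_first = min(f.start for f in cds_feats)
            cds_last = max(f.end for f in cds_feats)
        cds_start = mrna_offset(cds_first)
        cds_end = mrna_offset(cds_last) + 1
        if (cds_end - cds_start) % 3:
            cds_end = None  # partial CDS annotation; keep the start only
        out[tid] = Transcript(
            transcript_id=tid,
            gene_id=gene_id,
            exons=tuple(exons),
            introns=tuple(introns),
            cds_start=cds_start,
            cds_end=cds_end,
        )
    return out
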