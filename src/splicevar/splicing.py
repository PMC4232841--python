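"""Apply splice events to a transcript's block structure.

The engine edits the exon/intron block list in a single pass, so combined
events are order-independent by construction.  Alongside the variant mRNA
it produces:

* ``coord_map`` — for every reference spliced-mRNA position, its image in
  the variant mRNA, or ``None`` where the event deleted the position;
* ``modified_regions`` — half-open intervals of the variant mRNA that
  differ from the reference splice form.  Insertions (retained introns,
  splice-site extensions) cover the inserted bases; pure deletions (skips,
  truncations) leave a zero-length junction mark so downstream logic can
  still ask whether a codon spans the edit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import CombinedEvent, Event, EventType, SpliceEvent, Transcript, validate_event

__all__ = [
    "VariantTranscript",
    "splice_reference",
    "apply_event",
    "apply_combined",
    "map_position",
]


@dataclass(frozen=True)
class VariantTranscript:
    sequence: str
    source_transcript_id: str
    event_id: str
    modified_regions: tuple[tuple[int, int], ...]
    coord_map: tuple[int | None, ...]  # reference position -> variant position

    def __post_init__(self) -> None:
        mapped = [p for p in self.coord_map if p is not None]
        if any(b < a for a, b in zip(mapped, mapped[1:])):
            raise ValueError("coord_map is not strictly increasing")


def splice_reference(t: Transcript) -> str:
    """Reference mature mRNA: exon sequences concatenated in order."""
    return "".join(t.exons)


def _edit_plan(t: Transcript, events: tuple[SpliceEvent, ...], event_id: str):
    skip: set[int] = set()
    retain: set[int] = set()
    acceptor: dict[int, int] = {}
    donor: dict[int, int] = {}
    for e in events:
        problems = validate_event(t, e)
        if problems:
            raise ValueError(f"invalid event {event_id}: " + "; ".join(problems))
        if e.event_type is EventType.EXON_SKIP:
            i, j = e.skip_range
            skip.update(range(i, j + 1))
        elif e.event_type is EventType.ALT_3SS:
            acceptor[e.exon] = e.shift
        elif e.event_type is EventType.ALT_5SS:
            donor[e.exon] = e.shift
        elif e.event_type is EventType.INTRON_RETAIN:
            retain.add(e.intron)
    return skip, retain, acceptor, donor


def _apply(t: Transcript, events: tuple[SpliceEvent, ...], event_id: str) -> VariantTranscript:
    skip, retain, acceptor, donor = _edit_plan(t, events, event_id)
    offsets = t.exon_offsets
    n = len(t.exons)

    pieces: list[str] = []
    coord_map: list[int | None] = [None] * t.spliced_length
    regions: set[tuple[int, int]] = set()
    pos = 0  # current variant-mRNA position
    deletion_pending = False  # emit one junction mark per maximal deleted run

    def emit_reference(ref_start: int, seq: str) -> None:
        nonlocal pos, deletion_pending
        if deletion_pending:
            regions.add((pos, pos))
            deletion_pending = False
        for k in range(len(seq)):
            coord_map[ref_start + k] = pos + k
        pieces.append(seq)
        pos += len(seq)

    def emit_insertion(seq: str) -> None:
        nonlocal pos, deletion_pending
        if deletion_pending:
            regions.add((pos, pos))
            deletion_pending = False
        regions.add((pos, pos + len(seq)))
        pieces.append(seq)
        pos += len(seq)

    for i in range(n):
        if i in skip:
            deletion_pending = True
        else:
            exon = t.exons[i]
            start = offsets[i]
            a_shift = acceptor.get(i, 0)
            d_shift = donor.get(i, 0)
            if a_shift < 0:
                emit_insertion(t.introns[i - 1][a_shift:])
            elif a_shift > 0:
                deletion_pending = True
            core_start = max(a_shift, 0)
            core_end = len(exon) + min(d_shift, 0)
            emit_reference(start + core_start, exon[core_start:core_end])
            if d_shift < 0:
                deletion_pending = True
            elif d_shift > 0:
                emit_insertion(t.introns[i][:d_shift])
        if i < n - 1 and i in retain:
            emit_insertion(t.introns[i])
    if deletion_pending:
        regions.add((pos, pos))

    return VariantTranscript(
        sequence="".join(pieces),
        source_transcript_id=t.transcript_id,
        event_id=event_id,
        modified_regions=tuple(sorted(regions)),
        coord_map=tuple(coord_map),
    )


def apply_event(t: Transcript, e: SpliceEvent) -> VariantTranscript:
    """Apply a single splice event; see module docstring for semantics."""
    return _apply(t, (e,), e.event_id)


def apply_combined(t: Transcript, c: CombinedEvent) -> VariantTranscript:
    """Apply all constituents of a combined event in one pass over the
    block structure (never sequentially on remapped coordinates)."""
    problems = validate_event(t, c)
    # constituent-level problems re-surface in _apply; only reject the
    # combined-level ones (overlap, ordering, arity) here
    combined_level = [p for p in problems if "overlap" in p or "ordered" in p or ">= 2" in p]
    if combined_level:
        raise ValueError(f"invalid combined event {c.event_id}: " + "; ".join(combined_level))
    return _apply(t, c.events, c.event_id)


def map_position(v: VariantTranscript, ref_pos: int) -> int | None:
    """Image of a reference spliced-mRNA position in the variant mRNA, or
    ``None`` when the event deleted it."""
    if not 0 <= ref_pos < len(v.coord_map):
        raise IndexError(f"ref_pos {ref_pos} outside 0..{len(v.coord_map) - 1}")
    return v.coord_map[ref_pos]
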