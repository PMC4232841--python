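"""Shared fixtures and random generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from splicevar import CombinedEvent, EventType, SpliceEvent, Transcript
from splicevar.model import _claims

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture
def toy_transcript() -> Transcript:
    """Three-exon toy whose CDS spans the whole mRNA (MAEF*)."""
    return Transcript(
        transcript_id="NM_1",
        gene_id="G1",
        exons=("ATGGCA", "GAATTC", "TAA"),
        introns=("GTAAGT", "GTCAGT"),
        cds_start=0,
        cds_end=15,
    )


def random_transcript(rng: np.random.Generator, max_exons: int = 8) -> Transcript:
    n = int(rng.integers(2, max_exons + 1))
    exons = tuple(
        "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 61)))) for _ in range(n)
    )
    introns = tuple(
        "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 31))))
        for _ in range(n - 1)
    )
    return Transcript(
        transcript_id=f"RT{int(rng.integers(1e6)):06d}",
        gene_id="G",
        exons=exons,
        introns=introns,
        cds_start=0,
        cds_end=None,
    )


def random_event(rng: np.random.Generator, t: Transcript, event_id: str = "E") -> SpliceEvent:
    """A uniformly random *valid* simple event on the transcript."""
    n = len(t.exons)
    while True:
        kind = [
            EventType.EXON_SKIP,
            EventType.ALT_3SS,
            EventType.ALT_5SS,
            EventType.INTRON_RETAIN,
        ][int(rng.integers(4))]
        if kind is EventType.EXON_SKIP:
            i = int(rng.integers(n))
            j = int(rng.integers(i, n))
            return SpliceEvent(event_id, t.transcript_id, kind, {"skip": (i, j)})
        if kind is EventType.ALT_3SS and n >= 2:
            i = int(rng.integers(1, n))
            lo, hi = -len(t.introns[i - 1]), len(t.exons[i]) - 1
            s = int(rng.integers(lo, hi + 1))
            if s:
                return SpliceEvent(event_id, t.transcript_id, kind, {"exon": i, "shift": s})
        if kind is EventType.ALT_5SS and n >= 2:
            i = int(rng.integers(0, n - 1))
            lo, hi = -(len(t.exons[i]) - 1), len(t.introns[i])
            s = int(rng.integers(lo, hi + 1))
            if s:
                return SpliceEvent(event_id, t.transcript_id, kind, {"exon": i, "shift": s})
        if kind is EventType.INTRON_RETAIN and n >= 2:
            return SpliceEvent(
                event_id, t.transcript_id, kind, {"intron": int(rng.integers(n - 1))}
            )


def random_combined(
    rng: np.random.Generator, t: Transcript, event_id: str = "C", max_tries: int = 60
) -> CombinedEvent | None:
    """Two or three simple events with pairwise-disjoint footprints."""
    from splicevar.model import _anchor

    for _ in range(max_tries):
        k = int(rng.integers(2, 4))
        chosen: list[SpliceEvent] = []
        claimed: set = set()
        for idx in range(k):
            e = random_event(rng, t, f"{event_id}.{idx}")
            c = _claims(e)
            if c & claimed:
                break
            claimed |= c
            chosen.append(e)
        if len(chosen) == k:
            chosen.sort(key=_anchor)
            return CombinedEvent(event_id, t.transcript_id, tuple(chosen))
    return None
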