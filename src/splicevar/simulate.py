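"""Seeded synthetic gene models, splice events and peptide tables with
ground truth.

Every stage of the pipeline can be exercised without downloads: the
generator plants events with known consequences and records, per event,
the expected variant protein, the expected variant-unique tryptic
peptides, and the expected TIS classification.  All expectations are
computed by this module's own oracles — a token-stream block rewriter, a
regex-driven brute-force ORF scan, Biopython translation, and an O(n²)
substring digest enumerator — which share no code with the splice, ORF or
digestion engines they cross-validate.

The ``tis-rich`` preset cycles gene archetypes so that every TIS category
occurs often: start-exon skips resolved by a downstream in-frame ATG
(category A), retained introns that kill the reference ORF and carry the
new start themselves (category B), and retained 5'UTR introns with an
upstream in-frame ATG reading through into the CDS (category C), mixed
with internal events that leave the start untouched.  The ``default``
preset plants only internal events at the transcriptome-like type mix
(35/29/25/11% skip / alt-3' / alt-5' / retention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .database import VariantDatabase
from .model import CombinedEvent, Event, EventType, SpliceEvent, Transcript, validate_event

__all__ = [
    "FixtureTruth",
    "SyntheticStudy",
    "generate_gene",
    "generate_events",
    "generate_cohort",
    "simulate_observed_peptides",
]

_STOPS = ("TAA", "TAG", "TGA")

# Codons used for constructed regions: no stop can arise within or across
# any juxtaposition, no ATG within or across (none ends in A or AT), and
# none encodes K or R, so planted lysines (AAA) control tryptic sites.
_SAFE_CODONS = ["GCC", "GGC", "CCG", "TCC", "ACC", "GTC", "GAC", "GAG", "TTC", "CAC"]
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

_DEFAULT_MIX: Mapping[EventType, float] = {
    EventType.EXON_SKIP: 0.35,
    EventType.ALT_3SS: 0.29,
    EventType.ALT_5SS: 0.25,
    EventType.INTRON_RETAIN: 0.11,
}


# ---------------------------------------------------------------------------
# Independent oracles


def _oracle_variant(t: Transcript, events: Sequence[SpliceEvent]):
    """Token-stream block rewriter: returns (sequence, coord_map, regions)
    with the same semantics as the splice engine but rebuilt from scratch
    as an annotated-token fold."""
    skip: set[int] = set()
    retain: set[int] = set()
    acc: dict[int, int] = {}
    don: dict[int, int] = {}
    for e in events:
        kind = e.event_type
        if kind is EventType.EXON_SKIP:
            lo, hi = e.skip_range
            skip |= set(range(lo, hi + 1))
        elif kind is EventType.ALT_3SS:
            acc[e.exon] = e.shift
        elif kind is EventType.ALT_5SS:
            don[e.exon] = e.shift
        elif kind is EventType.INTRON_RETAIN:
            retain.add(e.intron)

    offsets = t.exon_offsets
    # tokens: ("ref", seq, ref_start) | ("ins", seq) | ("del",)
    tokens: list[tuple] = []
    for i, exon in enumerate(t.exons):
        if i in skip:
            tokens.append(("del",))
        else:
            a = acc.get(i, 0)
            d = don.get(i, 0)
            if a < 0:
                tokens.append(("ins", t.introns[i - 1][a:]))
            elif a > 0:
                tokens.append(("del",))
            lo, hi = max(a, 0), len(exon) + min(d, 0)
            tokens.append(("ref", exon[lo:hi], offsets[i] + lo))
            if d < 0:
                tokens.append(("del",))
            elif d > 0:
                tokens.append(("ins", t.introns[i][:d]))
        if i in retain and i < len(t.exons) - 1:
            tokens.append(("ins", t.introns[i]))

    out: list[str] = []
    coord: list[int | None] = [None] * t.spliced_length
    regions: set[tuple[int, int]] = set()
    pending = False
    pos = 0
    for tok in tokens:
        if tok[0] == "del":
            pending = True
            continue
        if pending:
            regions.add((pos, pos))
            pending = False
        if tok[0] == "ins":
            regions.add((pos, pos + len(tok[1])))
            out.append(tok[1])
            pos += len(tok[1])
        else:
            _, seq, start = tok
            for k in range(len(seq)):
                coord[start + k] = pos + k
            out.append(seq)
            pos += len(seq)
    if pending:
        regions.add((pos, pos))
    return "".join(out), coord, tuple(sorted(regions))


def _oracle_orfs(seq: str) -> list[tuple[int, int]]:
    """Brute-force ATG→stop scan; (start, end) of stop-terminated ORFs."""
    found = []
    for m in re.finditer("ATG", seq):
        start = m.start()
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos : pos + 3] in _STOPS:
                found.append((start, pos + 3))
                break
    return found


def _oracle_largest_orf(seq: str) -> tuple[int, int] | None:
    orfs = _oracle_orfs(seq)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o[1] - o[0], -o[0]))


def _oracle_translate(seq: str, start: int, end: int) -> str:
    aa = str(Seq(seq[start:end]).translate())
    return aa[:-1] if aa.endswith("*") else aa


def _oracle_peptides(protein: str, max_missed: int = 2, min_length: int = 7) -> set[str]:
    """Every substring that is a fully tryptic peptide (no proline
    restriction) with at most ``max_missed`` internal K/R sites."""
    n = len(protein)
    out: set[str] = set()
    for a in range(n):
        if a != 0 and protein[a - 1] not in "KR":
            continue
        for b in range(a + min_length, n + 1):
            if b != n and protein[b - 1] not in "KR":
                continue
            internal = sum(1 for k in range(a, b - 1) if protein[k] in "KR")
            if internal <= max_missed:
                out.add(protein[a:b])
    return out


def _common_suffix(a: str, b: str) -> int:
    # reversed-commonprefix formulation, distinct from the pipeline's loop
    import os

    return len(os.path.commonprefix([a[::-1], b[::-1]]))


# ---------------------------------------------------------------------------
# Ground truth


@dataclass(frozen=True)
class FixtureTruth:
    """Expected downstream results for one planted event."""

    event_id: str
    event_type: EventType | str
    variant_protein: str
    unique_peptides: tuple[str, ...]
    is_tis: bool
    tis_category: str | None
    first_atg_downstream: bool | None
    wilson_model: bool | None
    orf_disrupting: bool | None
    seed: int = 0


def _truth_for_event(
    t: Transcript,
    event: Event,
    reference_universe: set[str],
    reference_proteins: Mapping[str, str],
    max_missed: int = 2,
    min_length: int = 7,
) -> FixtureTruth | None:
    """Oracle-computed expectations; ``None`` when the event yields no
    stop-terminated ORF or a product identical to the reference protein."""
    subs = event.events if isinstance(event, CombinedEvent) else (event,)
    mrna, coord, regions = _oracle_variant(t, subs)
    orf = _oracle_largest_orf(mrna)
    if orf is None:
        return None
    s, orf_end = orf
    protein = _oracle_translate(mrna, s, orf_end)
    ref_protein = reference_proteins[t.transcript_id]
    if protein == ref_protein:
        return None

    peptides = _oracle_peptides(protein, max_missed, min_length)
    unique = tuple(sorted(p for p in peptides if p not in reference_universe))

    r = coord[t.cds_start]
    alt_tis = r is None or s != r
    nterm_unique = any(protein.startswith(p) for p in unique)
    is_tis = alt_tis and nterm_unique

    category = first_atg = wilson = disrupting = None
    if is_tis:
        if r is not None and s < r:
            category = "C_upstream"
        else:
            k = len(protein) - _common_suffix(protein, ref_protein)
            span_end = s + 3 * max(k, 1)
            hit = any(
                (a == b and s < a < span_end) or (a != b and a < span_end and b > s)
                for a, b in regions
            )
            category = "B_downstream_start_affected" if hit else "A_downstream"

        boundary = max((b for _, b in regions), default=0)
        m = re.compile("ATG").search(mrna, boundary)
        first_atg = m is not None and m.start() == s

        cds_end = min(t.cds_start + 3 * (len(ref_protein) + 1), t.spliced_length)
        dels = sum(1 for p in range(t.cds_start, cds_end) if coord[p] is None)
        var_to_ref = {vp: rp for rp, vp in enumerate(coord) if vp is not None}
        ins = 0
        for a, b in regions:
            if a == b:
                continue
            nxt = min((vp for vp in var_to_ref if vp >= b), default=None)
            if nxt is not None and t.cds_start < var_to_ref[nxt] < cds_end:
                ins += b - a
        m_end = max((b for _, b in regions), default=0)
        idx = max(0, -(-(m_end - s) // 3)) if m_end > s else 0
        tail = protein[idx:]
        stop_hit = False
        if r is not None:
            for p in range(r, s + 3 * idx - 2, 3):
                if mrna[p : p + 3] in _STOPS:
                    stop_hit = True
                    break
        wilson = (
            (ins - dels) % 3 == 0
            and bool(tail)
            and ref_protein.endswith(tail)
            and not stop_hit
        )
        disrupting = not wilson

    return FixtureTruth(
        event_id=event.event_id,
        event_type=event.event_type if isinstance(event, SpliceEvent) else "CASE",
        variant_protein=protein,
        unique_peptides=unique,
        is_tis=is_tis,
        tis_category=category,
        first_atg_downstream=first_atg,
        wilson_model=wilson,
        orf_disrupting=disrupting,
    )


# ---------------------------------------------------------------------------
# Gene construction


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _utr_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """UTR filler kept free of both ATG and stop triples at every offset,
    so planted ORFs stay the largest."""
    out: list[str] = []
    while len(out) < n:
        c = "ACGT"[int(rng.integers(4))]
        if "".join(out[-2:]) + c in ("ATG",) + _STOPS:
            continue
        out.append(c)
    return "".join(out)


def _safe_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n))


def _body_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n))


def _cut(seq: str, lengths: Sequence[int]) -> list[str]:
    parts, pos = [], 0
    for ln in lengths:
        parts.append(seq[pos : pos + ln])
        pos += ln
    return parts


def generate_gene(
    seed: int,
    n_exons: int | None = None,
    exon_len: tuple[int, int] = (30, 120),
    intron_len: tuple[int, int] = (9, 60),
    gc: float = 0.5,
    max_retries: int = 50,
) -> Transcript:
    """Random sequence-backed gene: ATG at a sampled CDS start, random
    non-stop body codons, in-frame stop in the final exon.  Deterministic
    under the seed; raises after bounded retries if the constraints cannot
    be met (e.g. the largest reference ORF is not the annotated CDS)."""
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        n = int(n_exons or rng.integers(3, 7))
        lengths = [int(rng.integers(exon_len[0], exon_len[1] + 1)) for _ in range(n)]
        total = sum(lengths)
        utr5 = int(rng.integers(3, max(4, lengths[0] - 3)))
        last_start = total - lengths[-1]
        stop_end = int(rng.integers(last_start + 6, total + 1))
        stop_end -= (stop_end - utr5) % 3
        if stop_end - utr5 < 36 or stop_end <= last_start:
            continue
        n_body = (stop_end - utr5) // 3 - 2
        mrna = (
            _utr_seq(rng, utr5, gc)
            + "ATG"
            + _body_codons(rng, n_body)
            + str(rng.choice(_STOPS))
            + _utr_seq(rng, total - stop_end, gc)
        )
        t = Transcript(
            transcript_id=f"SYNT{seed:07d}",
            gene_id=f"GENE{seed:07d}",
            exons=tuple(_cut(mrna, lengths)),
            introns=tuple(
                _random_seq(rng, int(rng.integers(intron_len[0], intron_len[1] + 1)), gc)
                for _ in range(n - 1)
            ),
            cds_start=utr5,
            cds_end=stop_end,
        )
        if _oracle_largest_orf(t.mrna) == (utr5, stop_end):
            return t
    raise RuntimeError(f"gene construction failed for seed {seed}")


# ---------------------------------------------------------------------------
# Archetype genes (gene and event built together)


def _nterm_tag_codons(rng: np.random.Generator) -> str:
    """Nine safe codons then a lysine: gives the new start a >=7-residue
    N-terminal tryptic peptide of novel composition."""
    return _safe_codons(rng, 9) + "AAA"


def _archetype_A(rng: np.random.Generator, idx: int) -> tuple[Transcript, SpliceEvent]:
    """Skip of the start-containing exon; an in-frame ATG planted two
    exons downstream becomes the new start (category A).  Half the genes
    delete a multiple of three within the CDS (amino-end-only isoforms)."""
    lengths = [36, int(rng.integers(45, 90)), int(rng.integers(45, 90)), 90, 60]
    utr5 = 6
    frame_preserving = idx % 2 == 0
    d = lengths[1] - utr5  # CDS nucleotides removed by skipping exon 1
    if frame_preserving:
        lengths[1] += (3 - d % 3) % 3
    elif d % 3 == 0:
        lengths[1] += 1
    cds_start = lengths[0] + utr5  # inside exon 1
    total = sum(lengths)
    stop_end = total - 6
    stop_end -= (stop_end - cds_start) % 3
    n_body = (stop_end - cds_start) // 3 - 2
    body = _body_codons(rng, n_body)
    # plant M + tag early in exon 3, on a codon boundary, preceded by a
    # non-K/R residue so the new N-terminal peptide is not tryptic in the
    # reference
    exon3_off = lengths[0] + lengths[1] + lengths[2]
    k = ((exon3_off - cds_start + 5) // 3 + 1) * 3  # codon-aligned body offset
    plant = "GGC" + "ATG" + _nterm_tag_codons(rng)
    body = body[: k - 3] + plant + body[k - 3 + len(plant) :]
    mrna = (
        _utr_seq(rng, lengths[0])  # exon 0: pure UTR
        + _utr_seq(rng, utr5)
        + "ATG"
        + body
        + str(rng.choice(_STOPS))
        + _utr_seq(rng, total - stop_end)
    )
    t = Transcript(
        transcript_id=f"SYNA{idx:05d}",
        gene_id=f"GENA{idx:05d}",
        exons=tuple(_cut(mrna, lengths)),
        introns=tuple(_random_seq(rng, int(rng.integers(20, 50)), 0.5) for _ in range(4)),
        cds_start=cds_start,
        cds_end=stop_end,
    )
    event = SpliceEvent(
        event_id=f"EVA{idx:05d}",
        transcript_id=t.transcript_id,
        event_type=EventType.EXON_SKIP,
        params={"skip": (1, 1)},
        support_count=int(rng.integers(2, 12)),
    )
    return t, event


def _archetype_B(rng: np.random.Generator, idx: int) -> tuple[Transcript, SpliceEvent]:
    """Retention of an early-CDS intron that carries an in-frame stop
    (killing the reference ORF) followed by an ATG reading through into
    the remaining CDS (category B)."""
    lengths = [60, int(rng.integers(120, 180)), 60]
    utr5 = 9
    cds_start = utr5
    boundary = lengths[0]  # exon0/exon1 junction, inside the CDS
    pad = (3 - (boundary - cds_start) % 3) % 3  # put junction on a codon boundary
    lengths[0] += pad
    boundary = lengths[0]
    total = sum(lengths)
    stop_end = total - 6
    stop_end -= (stop_end - cds_start) % 3
    n_body = (stop_end - cds_start) // 3 - 2
    mrna = (
        _utr_seq(rng, utr5, 0.5)
        + "ATG"
        + _body_codons(rng, n_body)
        + str(rng.choice(_STOPS))
        + _utr_seq(rng, total - stop_end, 0.5)
    )
    # intron 0: safe filler, an in-frame TAA, then ATG + tag codons to the end
    n_tail = int(rng.integers(4, 8))
    intron0 = _safe_codons(rng, 2) + "TAA" + "ATG" + _nterm_tag_codons(rng) + _safe_codons(rng, n_tail)
    t = Transcript(
        transcript_id=f"SYNB{idx:05d}",
        gene_id=f"GENB{idx:05d}",
        exons=tuple(_cut(mrna, lengths)),
        introns=(intron0, _random_seq(rng, int(rng.integers(20, 50)), 0.5)),
        cds_start=cds_start,
        cds_end=stop_end,
    )
    event = SpliceEvent(
        event_id=f"EVB{idx:05d}",
        transcript_id=t.transcript_id,
        event_type=EventType.INTRON_RETAIN,
        params={"intron": 0},
        support_count=int(rng.integers(2, 12)),
    )
    return t, event


def _archetype_C(rng: np.random.Generator, idx: int) -> tuple[Transcript, SpliceEvent]:
    """Retention of a 5'UTR intron carrying an ATG that reads in frame
    into the annotated CDS: the variant initiates upstream of the intact
    reference start (category C)."""
    u1 = 3 * int(rng.integers(0, 3))  # exon-1 bases upstream of the start codon
    lengths = [30, int(rng.integers(120, 180)), 60]
    cds_start = lengths[0] + u1
    total = sum(lengths)
    stop_end = total - 6
    stop_end -= (stop_end - cds_start) % 3
    n_body = (stop_end - cds_start) // 3 - 2
    mrna = (
        _utr_seq(rng, lengths[0], 0.5)
        + _safe_codons(rng, u1 // 3)
        + "ATG"
        + _body_codons(rng, n_body)
        + str(rng.choice(_STOPS))
        + _utr_seq(rng, total - stop_end, 0.5)
    )
    intron0 = _safe_codons(rng, int(rng.integers(2, 5))) + "ATG" + _nterm_tag_codons(rng)
    t = Transcript(
        transcript_id=f"SYNC{idx:05d}",
        gene_id=f"GENC{idx:05d}",
        exons=tuple(_cut(mrna, lengths)),
        introns=(intron0, _random_seq(rng, int(rng.integers(20, 50)), 0.5)),
        cds_start=cds_start,
        cds_end=stop_end,
    )
    event = SpliceEvent(
        event_id=f"EVC{idx:05d}",
        transcript_id=t.transcript_id,
        event_type=EventType.INTRON_RETAIN,
        params={"intron": 0},
        support_count=int(rng.integers(2, 12)),
    )
    return t, event


def _internal_event(
    rng: np.random.Generator, t: Transcript, etype: EventType, event_id: str
) -> SpliceEvent | None:
    """Sample a valid internal (start-preserving) event of the requested
    type; frame-preserving shifts keep the reference ORF the largest."""
    n = len(t.exons)
    offsets = t.exon_offsets
    # exons fully inside the CDS, excluding the first and last
    internal = [
        i
        for i in range(1, n - 1)
        if offsets[i] > t.cds_start and offsets[i] + len(t.exons[i]) < (t.cds_end or 0)
    ]
    if etype is EventType.EXON_SKIP:
        frame_ok = [i for i in internal if len(t.exons[i]) % 3 == 0]
        pool = frame_ok or internal
        if not pool:
            return None
        i = int(pool[rng.integers(len(pool))])
        return SpliceEvent(event_id, t.transcript_id, etype, {"skip": (i, i)})
    if etype is EventType.ALT_3SS:
        pool = [i for i in internal if len(t.exons[i]) > 10]
        if not pool:
            return None
        i = int(pool[rng.integers(len(pool))])
        shift = 3 * int(rng.integers(1, min(4, (len(t.exons[i]) - 1) // 3) + 1))
        return SpliceEvent(event_id, t.transcript_id, etype, {"exon": i, "shift": shift})
    if etype is EventType.ALT_5SS:
        pool = [i for i in internal if len(t.exons[i]) > 10]
        if not pool:
            return None
        i = int(pool[rng.integers(len(pool))])
        shift = -3 * int(rng.integers(1, min(4, (len(t.exons[i]) - 1) // 3) + 1))
        return SpliceEvent(event_id, t.transcript_id, etype, {"exon": i, "shift": shift})
    if etype is EventType.INTRON_RETAIN:
        pool = [
            k
            for k in range(len(t.introns))
            if offsets[k + 1] > t.cds_start
            and offsets[k + 1] < (t.cds_end or 0)
            and len(t.introns[k]) % 3 == 0
        ]
        if not pool:
            return None
        k = int(pool[rng.integers(len(pool))])
        return SpliceEvent(event_id, t.transcript_id, etype, {"intron": k})
    return None


def generate_events(
    t: Transcript,
    mix: Mapping[EventType, float] | None = None,
    n: int = 1,
    seed: int = 0,
) -> tuple[list[SpliceEvent], dict[str, FixtureTruth]]:
    """Sample ``n`` valid events on one transcript per the type mix and
    compute per-event truth against this gene's own reference protein.
    Types with no valid placement are skipped with a warning."""
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    mix = dict(mix or _DEFAULT_MIX)
    types = list(mix)
    weights = np.array([mix[k] for k in types], dtype=float)
    weights /= weights.sum()
    ref_prot = _oracle_translate(t.mrna, t.cds_start, t.cds_end or t.spliced_length)
    universe = _oracle_peptides(ref_prot)
    events: list[SpliceEvent] = []
    truths: dict[str, FixtureTruth] = {}
    for i in range(n):
        etype = types[int(rng.choice(len(types), p=weights))]
        e = _internal_event(rng, t, etype, f"{t.transcript_id}.E{i}")
        if e is None:
            _warnings.warn(f"no valid {etype.value} placement on {t.transcript_id}")
            continue
        e = SpliceEvent(
            e.event_id, e.transcript_id, e.event_type, e.params,
            support_count=int(rng.integers(2, 12)),
        )
        if validate_event(t, e):
            continue
        truth = _truth_for_event(
            t, e, universe, {t.transcript_id: ref_prot}
        )
        if truth is None:
            continue
        events.append(e)
        truths[e.event_id] = truth
    return events, truths


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class SyntheticStudy:
    transcripts: dict[str, Transcript]
    events: list[Event]
    truths: dict[str, FixtureTruth]
    reference_proteome: list[tuple[str, str]]
    seed: int = 0

    @property
    def reference_records(self) -> list[tuple[str, str]]:
        return list(self.reference_proteome)


def generate_cohort(
    seed: int,
    n_genes: int = 200,
    preset: str = "tis-rich",
    events_per_gene: int = 1,
) -> SyntheticStudy:
    """Build a cohort of genes with planted events and cohort-wide truth.

    ``tis-rich`` cycles archetypes A/B/C/generic/generic/CASE; ``default``
    plants only internal events at the transcriptome-like mix.  Uniqueness
    in the truth is judged against the tryptic universe of the whole
    cohort's reference proteome, exactly as the pipeline will see it.
    """
    rng = np.random.default_rng(seed)
    transcripts: dict[str, Transcript] = {}
    events: list[Event] = []
    gene_events: list[tuple[Transcript, Event]] = []

    cycle = ["A", "B", "C", "generic", "generic", "case"] if preset == "tis-rich" else ["generic"]
    for g in range(n_genes):
        kind = cycle[g % len(cycle)]
        sub_rng = np.random.default_rng(rng.integers(1, 2**31 - 1))
        if kind == "A":
            t, e = _archetype_A(sub_rng, g)
            gene_events.append((t, e))
        elif kind == "B":
            t, e = _archetype_B(sub_rng, g)
            gene_events.append((t, e))
        elif kind == "C":
            t, e = _archetype_C(sub_rng, g)
            gene_events.append((t, e))
        else:
            t = generate_gene(int(sub_rng.integers(1, 2**31 - 1)), n_exons=5)
            t = Transcript(
                transcript_id=f"SYNG{g:05d}",
                gene_id=f"GENG{g:05d}",
                exons=t.exons,
                introns=tuple(
                    _safe_codons(sub_rng, max(3, len(i) // 3)) for i in t.introns
                ),
                cds_start=t.cds_start,
                cds_end=t.cds_end,
            )
            if kind == "case":
                first = _internal_event(sub_rng, t, EventType.EXON_SKIP, f"EVG{g:05d}.0")
                second = _internal_event(
                    sub_rng, t, EventType.INTRON_RETAIN, f"EVG{g:05d}.1"
                )
                if first is None or second is None:
                    continue
                subs = tuple(
                    sorted((first, second), key=lambda s: (s.params.get("skip", (99,))[0]
                                                           if s.event_type is EventType.EXON_SKIP
                                                           else s.params["intron"]))
                )
                combined = CombinedEvent(
                    event_id=f"EVG{g:05d}",
                    transcript_id=t.transcript_id,
                    events=subs,
                    support_count=int(sub_rng.integers(2, 12)),
                )
                if validate_event(t, combined):
                    continue
                gene_events.append((t, combined))
                continue
            etypes = list(_DEFAULT_MIX)
            w = np.array([_DEFAULT_MIX[k] for k in etypes])
            w = w / w.sum()
            etype = etypes[int(sub_rng.choice(len(etypes), p=w))]
            e = _internal_event(sub_rng, t, etype, f"EVG{g:05d}")
            if e is None:
                continue
            e = SpliceEvent(
                e.event_id, e.transcript_id, e.event_type, e.params,
                support_count=int(sub_rng.integers(2, 12)),
            )
            gene_events.append((t, e))

    reference_proteins: dict[str, str] = {}
    for t, e in gene_events:
        transcripts[t.transcript_id] = t
        events.append(e)
        reference_proteins[t.transcript_id] = _oracle_translate(
            t.mrna, t.cds_start, t.cds_end or t.spliced_length
        )

    universe: set[str] = set()
    for prot in reference_proteins.values():
        universe |= _oracle_peptides(prot)

    truths: dict[str, FixtureTruth] = {}
    kept_events: list[Event] = []
    for t, e in gene_events:
        truth = _truth_for_event(t, e, universe, reference_proteins)
        if truth is None:
            continue
        truths[e.event_id] = truth
        kept_events.append(e)

    proteome = [
        (f"REF_{tid}", reference_proteins[tid]) for tid in sorted(transcripts)
    ]
    return SyntheticStudy(
        transcripts=transcripts,
        events=kept_events,
        truths=truths,
        reference_proteome=proteome,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Observed-peptide simulation


def simulate_observed_peptides(
    db: VariantDatabase,
    detect_prob: float = 1.0,
    n_decoy_rows: int = 0,
    n_contaminant_rows: int = 0,
    seed: int = 0,
    max_missed: int = 2,
    min_length: int = 7,
) -> pd.DataFrame:
    """Emulate a filtered search-engine peptide table over the database.

    Every tryptic peptide of every database entry is emitted with
    probability ``detect_prob``; protein assignments are computed honestly
    from the database (variant and reference entries alike).  Decoy rows
    carry reversed sequences and a ``+`` Reverse flag; contaminant rows a
    ``+`` Potential contaminant flag.  Intensities are log-normal around
    1e7 (sigma one decade); scores are uniform on [40, 160].
    """
    rng = np.random.default_rng(seed)
    assignments: dict[str, set[str]] = {}
    for v in db.variants:
        for pep in _oracle_peptides(v.sequence, max_missed, min_length):
            assignments.setdefault(pep, set()).add(v.accession)
    for header, seq in db.reference_records:
        accession = header.split()[0]
        for pep in _oracle_peptides(seq, max_missed, min_length):
            assignments.setdefault(pep, set()).add(accession)

    rows = []
    for pep in sorted(assignments):
        if rng.random() >= detect_prob:
            continue
        rows.append(
            {
                "Sequence": pep,
                "Proteins": ";".join(sorted(assignments[pep])),
                "Score": round(float(rng.uniform(40, 160)), 2),
                "Intensity": round(10 ** float(rng.normal(7, 1)), 1),
                "Reverse": "",
                "Potential contaminant": "",
            }
        )
    all_peps = sorted(assignments)
    for k in range(n_decoy_rows):
        src = all_peps[int(rng.integers(len(all_peps)))] if all_peps else "SAMPLEPEPTIDEK"
        rows.append(
            {
                "Sequence": src[::-1],
                "Proteins": "REV__" + src[:6],
                "Score": round(float(rng.uniform(40, 160)), 2),
                "Intensity": round(10 ** float(rng.normal(7, 1)), 1),
                "Reverse": "+",
                "Potential contaminant": "",
            }
        )
    for k in range(n_contaminant_rows):
        seq = "".join(rng.choice(list("ACDEFGHILMNPQSTVWY"), size=10)) + "K"
        rows.append(
            {
                "Sequence": seq,
                "Proteins": f"CON__{k:03d}",
                "Score": round(float(rng.uniform(40, 160)), 2),
                "Intensity": round(10 ** float(rng.normal(7, 1)), 1),
                "Reverse": "",
                "Potential contaminant": "+",
            }
        )
    columns = ["Sequence", "Proteins", "Score", "Intensity", "Reverse", "Potential contaminant"]
    return pd.DataFrame(rows, columns=columns)
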