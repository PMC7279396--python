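"""Subclone read alignment, event extraction and allele collapsing.

Reads are near-full-length clones of the wild-type amplicon, so a global
affine-gap alignment is used (match +2, mismatch -3, gap open -10, gap
extend -1).  Gap runs become deletion/insertion events and maximal
mismatch runs become substitution events; all indels are left-aligned so
that reads representing the same mutation at different gap placements
collapse into one allele.

Events that do not touch either guide's attribution window are treated as
sequencing/PCR noise: they are excluded from the allele signature and the
"edited" call, but retained in a diagnostics channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .events import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    EditEvent,
    apply_events,
    event_list_signature,
    normalize_events,
)
from .locus import TargetLocus

MATCH = 2
MISMATCH = -3
GAP_OPEN = -10
GAP_EXTEND = -1

LENGTH_RATIO_RANGE = (0.3, 2.0)
IDENTITY_FLOOR = 0.60  # matching fraction of alignment columns


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class ReadAlignment:
    read_id: str
    sequence: str
    alignment: object | None
    identity: float
    alignable: bool
    reason: str = ""


@dataclass
class AlleleCall:
    allele_id: str
    events: tuple[EditEvent, ...]
    support: int
    edited: bool
    low_support: bool = False
    read_ids: tuple[str, ...] = ()

    @property
    def signature(self) -> tuple[str, ...]:
        return event_list_signature(self.events)


@dataclass
class ReadCall:
    read_id: str
    events: tuple[EditEvent, ...]        # guide-attributed events
    noise_events: tuple[EditEvent, ...]  # events outside both windows


@dataclass
class PlantCall:
    plant_id: str
    alleles: list[AlleleCall]
    reads: list[ReadCall]
    unalignable: list[ReadAlignment]

    @property
    def edited_alleles(self) -> list[AlleleCall]:
        return [a for a in self.alleles if a.edited]


def align_read(read: str, locus: TargetLocus, read_id: str = "read") -> ReadAlignment:
    """Globally align one read against the amplicon.

    Reads outside the accepted length ratio, or whose matching fraction
    over all alignment columns falls below the floor, are rejected as
    unalignable.
    """
    read = read.upper()
    L = len(locus.amplicon)
    ratio = len(read) / L if L else 0.0
    if not (LENGTH_RATIO_RANGE[0] <= ratio <= LENGTH_RATIO_RANGE[1]):
        return ReadAlignment(read_id, read, None, 0.0, False,
                             f"length ratio {ratio:.2f} outside range")
    aln = _ALIGNER.align(locus.amplicon, read)[0]
    matches = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for i in range(te - ts):
            if locus.amplicon[ts + i] == read[qs + i]:
                matches += 1
    # gap columns count against identity, so a read the aligner can only
    # shred into many short gapped segments falls below the floor
    identity = matches / max(aln.length, 1)
    if identity < IDENTITY_FLOOR:
        return ReadAlignment(read_id, read, aln, identity, False,
                             f"identity {identity:.2f} below floor")
    return ReadAlignment(read_id, read, aln, identity, True)


def extract_events(
    ra: ReadAlignment, locus: TargetLocus, noise_filter: bool = True
) -> tuple[tuple[EditEvent, ...], tuple[EditEvent, ...]]:
    """Normalized events from one alignment: (guide events, noise events).

    Gap runs become indels, maximal mismatch runs become substitution
    events; everything is left-aligned and guide-annotated.  With
    ``noise_filter`` on, events outside both attribution windows go to the
    noise channel instead of the main event list.
    """
    if not ra.alignable or ra.alignment is None:
        raise ValueError(f"read {ra.read_id} is unalignable: {ra.reason}")
    ref = locus.amplicon
    read = ra.sequence
    target_blocks, query_blocks = ra.alignment.aligned
    raw: list[EditEvent] = []
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        if prev_t is not None:
            if ts > prev_t:  # reference bases skipped -> deletion
                raw.append(EditEvent(start=prev_t, kind=DELETION,
                                     ref_span=ts - prev_t))
            if qs > prev_q:  # read bases skipped -> insertion
                raw.append(EditEvent(start=ts, kind=INSERTION, ref_span=0,
                                     alt_seq=read[prev_q:qs]))
        run_start = None
        for i in range(te - ts):
            if ref[ts + i] != read[qs + i]:
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                raw.append(EditEvent(start=ts + run_start, kind=SUBSTITUTION,
                                     ref_span=i - run_start,
                                     alt_seq=read[qs + run_start:qs + i]))
                run_start = None
        if run_start is not None:
            raw.append(EditEvent(start=ts + run_start, kind=SUBSTITUTION,
                                 ref_span=(te - ts) - run_start,
                                 alt_seq=read[qs + run_start:qe]))
        prev_t, prev_q = te, qe
    events = normalize_events(raw, locus)
    if not noise_filter:
        return events, ()
    kept = tuple(e for e in events if e.guide_hit != "none")
    noise = tuple(e for e in events if e.guide_hit == "none")
    return kept, noise


def collapse_alleles(
    read_calls: list[ReadCall], min_support: int = 1
) -> list[AlleleCall]:
    """Merge reads with identical normalized event lists into alleles.

    The WT allele is the empty-event allele.  Alleles below
    ``min_support`` are retained but flagged low-support.  Alleles are
    ordered by support (descending) then signature for determinism.
    """
    buckets: dict[tuple[str, ...], list[ReadCall]] = {}
    for rc in read_calls:
        buckets.setdefault(event_list_signature(rc.events), []).append(rc)
    items = sorted(buckets.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    alleles = []
    n_edited = 0
    for sig, members in items:
        edited = bool(sig)
        if edited:
            n_edited += 1
            allele_id = f"A{n_edited}"
        else:
            allele_id = "WT"
        alleles.append(AlleleCall(
            allele_id=allele_id,
            events=members[0].events,
            support=len(members),
            edited=edited,
            low_support=len(members) < min_support,
            read_ids=tuple(rc.read_id for rc in members),
        ))
    return alleles


def call_plant(
    reads: list[tuple[str, str]],
    locus: TargetLocus,
    plant_id: str = "plant",
    min_support: int = 1,
) -> PlantCall:
    """Full per-plant calling: align, extract, collapse.

    ``reads`` is a list of (read_id, sequence).
    """
    read_calls, unalignable = [], []
    for rid, seq in reads:
        ra = align_read(seq, locus, read_id=rid)
        if not ra.alignable:
            unalignable.append(ra)
            continue
        kept, noise = extract_events(ra, locus)
        read_calls.append(ReadCall(read_id=rid, events=kept, noise_events=noise))
    alleles = collapse_alleles(read_calls, min_support=min_support)
    return PlantCall(plant_id=plant_id, alleles=alleles, reads=read_calls,
                     unalignable=unalignable)


def reconstruct_read(allele: AlleleCall, locus: TargetLocus) -> str:
    """Apply an allele's events back onto the amplicon."""
    return apply_events(locus.amplicon, allele.events)
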