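"""Normalized edit events in reference (amplicon) coordinates.

An :class:`EditEvent` is the unit shared by the simulator, the caller and
all downstream tabulation: a deletion, insertion or substitution run,
left-aligned against the reference (VCF-style: an indel is shifted left
while the flanking reference base matches), annotated with its size class
and its guide attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .locus import TargetLocus

DELETION = "deletion"
INSERTION = "insertion"
SUBSTITUTION = "substitution"

SMALL_MAX = 15  # small <= 15 bp, large > 15 bp (mutation-spectrum classes)


@dataclass(frozen=True, order=True)
class EditEvent:
    start: int
    kind: str
    ref_span: int          # reference bp removed/replaced (0 for insertion)
    alt_seq: str = ""      # inserted or replacement bases
    guide_hit: str = "none"          # 'sg1' | 'sg2' | 'both' | 'none'
    inter_guide_dropout: bool = False

    @property
    def size(self) -> int:
        if self.kind == INSERTION:
            return len(self.alt_seq)
        return self.ref_span

    @property
    def size_class(self) -> str:
        return "small" if self.size <= SMALL_MAX else "large"

    @property
    def end(self) -> int:
        """End of the affected reference interval (half-open)."""
        return self.start + self.ref_span

    @property
    def net(self) -> int:
        """Signed length change contributed to the sequence."""
        if self.kind == DELETION:
            return -self.ref_span
        if self.kind == INSERTION:
            return len(self.alt_seq)
        return 0

    def signature(self) -> str:
        """Compact canonical string, e.g. ``del:120-202(82)``."""
        if self.kind == DELETION:
            return f"del:{self.start}-{self.end}({self.size})"
        if self.kind == INSERTION:
            return f"ins:{self.start}(+{self.size}:{self.alt_seq})"
        return f"sub:{self.start}-{self.end}({self.alt_seq})"


def left_align(event: EditEvent, reference: str, floor: int = 0) -> EditEvent:
    """Shift an indel left while the flanking reference base matches.

    ``floor`` bounds the shift so an indel never slides past a preceding
    event.  Substitution runs are positionally unambiguous and returned
    unchanged.
    """
    if event.kind == DELETION:
        s, k = event.start, event.ref_span
        while s > floor and reference[s - 1] == reference[s + k - 1]:
            s -= 1
        return replace(event, start=s)
    if event.kind == INSERTION:
        s, ins = event.start, event.alt_seq
        while s > floor and ins and reference[s - 1] == ins[-1]:
            ins = reference[s - 1] + ins[:-1]
            s -= 1
        return replace(event, start=s, alt_seq=ins)
    return event


def annotate(event: EditEvent, locus: TargetLocus) -> EditEvent:
    """Attach guide attribution and inter-guide-dropout status."""
    c1, c2 = locus.cut_positions
    hits = []
    for label, guide in (("sg1", locus.sg1), ("sg2", locus.sg2)):
        lo, hi = guide.attribution_window()
        if event.kind == INSERTION:
            touches = lo <= event.start <= hi
        else:
            touches = event.start <= hi and event.end > lo
        if touches:
            hits.append(label)
    guide_hit = "both" if len(hits) == 2 else (hits[0] if hits else "none")
    dropout = (
        event.kind == DELETION
        and event.start <= c1
        and event.end >= c2
    )
    return replace(event, guide_hit=guide_hit, inter_guide_dropout=dropout)


def normalize_events(
    events: list[EditEvent], locus: TargetLocus
) -> tuple[EditEvent, ...]:
    """Left-align, annotate and sort events into canonical order.

    Events are processed in start order; each indel left-aligns only down
    to the end of the preceding event, so normalization never reorders or
    merges events and applying the normalized list reproduces the same
    sequence as the raw list.
    """
    out = []
    floor = 0
    for e in sorted(events, key=lambda ev: (ev.start, ev.kind != INSERTION)):
        shifted = annotate(left_align(e, locus.amplicon, floor=floor), locus)
        out.append(shifted)
        floor = shifted.start if shifted.kind == INSERTION else shifted.end
    out.sort(key=lambda e: (e.start, e.kind, e.size))
    return tuple(out)


def apply_events(reference: str, events) -> str:
    """Apply non-overlapping events to the reference sequence.

    Events are applied right-to-left so reference coordinates stay valid.
    """
    # right-to-left; at equal start an insertion is applied after the
    # deletion/substitution there (the insertion lands 5' of that base)
    ordered = sorted(events,
                     key=lambda e: (e.start, e.kind != INSERTION),
                     reverse=True)
    seq = reference
    last_start = len(reference) + 1
    for e in ordered:
        if e.end > last_start:
            raise ValueError("overlapping events cannot be applied")
        if e.end > len(reference) or e.start < 0:
            raise ValueError(f"event {e.signature()} extends past the amplicon")
        if e.kind == DELETION:
            seq = seq[: e.start] + seq[e.end :]
        elif e.kind == INSERTION:
            seq = seq[: e.start] + e.alt_seq + seq[e.start :]
        else:
            if len(e.alt_seq) != e.ref_span:
                raise ValueError("substitution run length mismatch")
            seq = seq[: e.start] + e.alt_seq + seq[e.end :]
        last_start = e.start
    return seq


def event_list_signature(events) -> tuple[str, ...]:
    """Hashable signature of a normalized event list (allele identity)."""
    return tuple(e.signature() for e in events)
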