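"""Protein consequences of called alleles and significance classes.

An allele's events are clipped to the CDS segments, applied to the
wild-type coding sequence and translated with the standard code.
Significance follows a three-level hierarchy: a reading-frame shift (net
coding indel not divisible by 3) is the most significant, then an indel of
at least 15 bp without a shift, then everything else (small in-frame
indels and substitutions without a shift).

Note the two size thresholds are deliberately independent constants: the
mutation-spectrum size classes split at <=15/>15 bp while the significance
class uses >=15 bp, so a 15-bp indel is "small" in the spectrum table but
significant at the protein level.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from ._util import pct
from .events import DELETION, INSERTION, SUBSTITUTION, EditEvent
from .locus import TargetLocus

SIGNIFICANT_INDEL_MIN = 15  # bp, ">=" comparison

SIG_FRAMESHIFT = "significant_frameshift"
SIG_LARGE_INDEL = "significant_large_indel"
SIG_LESS = "less_significant"


@dataclass
class Consequence:
    frameshift: bool
    premature_stop: bool
    aa_changed: bool
    net_indel: int            # signed bp within the CDS
    significance: str
    large_indel: bool = False  # carries an indel of >= 15 bp
    partial_cds: bool = False  # some event only partly overlaps the CDS


def _wt_cds(locus: TargetLocus) -> str:
    cds = "".join(locus.amplicon[s:e] for s, e in locus.cds_segments)
    return cds[locus.cds_phase:]


def _downstream_tail(locus: TargetLocus) -> str:
    """Amplicon sequence 3' of the last CDS segment (frameshift read-through)."""
    return locus.amplicon[locus.cds_segments[-1][1]:]


def _clip_to_cds(event: EditEvent, locus: TargetLocus):
    """Map an event into CDS-relative coordinates, clipping at segment edges.

    Returns (cds_event | None, partial) where ``partial`` marks an event
    only partly inside the CDS; the clipped portion alone contributes to
    the coding change, mirroring how a deletion running off an exon only
    removes its exonic bases from the transcript.
    """
    offset = 0
    phase = locus.cds_phase
    for s, e in locus.cds_segments:
        if event.kind == INSERTION:
            if s < event.start < e:
                pos = offset + (event.start - s) - phase
                return EditEvent(start=pos, kind=INSERTION, ref_span=0,
                                 alt_seq=event.alt_seq), False
        else:
            lo = max(event.start, s)
            hi = min(event.end, e)
            if lo < hi:
                partial = not (s <= event.start and event.end <= e)
                pos = offset + (lo - s) - phase
                alt = ""
                if event.kind == SUBSTITUTION:
                    alt = event.alt_seq[lo - event.start: hi - event.start]
                return EditEvent(start=pos, kind=event.kind, ref_span=hi - lo,
                                 alt_seq=alt), partial
        offset += e - s
    return None, event.kind != INSERTION and any(
        max(event.start, s) < min(event.end, e)
        for s, e in locus.cds_segments)


def _first_stop(protein: str) -> int:
    i = protein.find("*")
    return i if i >= 0 else len(protein)


def classify_consequence(events, locus: TargetLocus) -> Consequence:
    """Protein consequence of one allele's (normalized) event list."""
    for e in events:
        if e.start < 0 or e.end > len(locus.amplicon):
            raise ValueError(f"event {e.signature()} extends past the amplicon")

    wt_cds = _wt_cds(locus)
    tail = _downstream_tail(locus)
    cds_events = []
    partial = False
    net = 0
    for e in sorted(events, key=lambda ev: ev.start):
        ce, part = _clip_to_cds(e, locus)
        partial = partial or part
        if ce is not None:
            cds_events.append(ce)
            net += ce.net

    mut_cds = wt_cds
    for ce in sorted(cds_events, key=lambda ev: ev.start, reverse=True):
        if ce.kind == DELETION:
            mut_cds = mut_cds[:ce.start] + mut_cds[ce.end:]
        elif ce.kind == INSERTION:
            mut_cds = mut_cds[:ce.start] + ce.alt_seq + mut_cds[ce.start:]
        else:
            mut_cds = mut_cds[:ce.start] + ce.alt_seq + mut_cds[ce.end:]

    def translate(seq: str) -> str:
        usable = seq[: len(seq) - len(seq) % 3]
        return str(Seq(usable).translate())

    wt_prot = translate(wt_cds + tail)
    mut_prot = translate(mut_cds + tail)
    wt_stop = _first_stop(wt_prot)
    mut_stop = _first_stop(mut_prot)

    frameshift = net % 3 != 0
    premature = mut_stop < wt_stop
    aa_changed = mut_prot[:mut_stop] != wt_prot[:wt_stop]

    has_large_indel = any(
        e.kind in (DELETION, INSERTION) and e.size >= SIGNIFICANT_INDEL_MIN
        for e in events
    )
    if frameshift:
        significance = SIG_FRAMESHIFT
    elif has_large_indel:
        significance = SIG_LARGE_INDEL
    else:
        significance = SIG_LESS

    return Consequence(frameshift=frameshift, premature_stop=premature,
                       aa_changed=aa_changed, net_indel=net,
                       significance=significance, large_indel=has_large_indel,
                       partial_cds=partial)


def consequence_table(consequences: list[Consequence],
                      gene: str = "gene") -> pd.DataFrame:
    """Per-gene counts/percentages of significance classes.

    Columns mirror the significance hierarchy: reading-frame shifts,
    >=15 bp indels (with or without a shift), their union ("significant")
    and the complement ("less significant").  Denominator = edited alleles.
    """
    n = len(consequences)
    n_fs = sum(c.frameshift for c in consequences)
    # the ">=15 bp indel" column counts alleles carrying such an indel
    # regardless of frameshift status; "significant" is the union
    n_large = sum(c.large_indel for c in consequences)
    n_sig = sum(1 for c in consequences if c.frameshift or c.large_indel)
    n_less = n - n_sig
    return pd.DataFrame([{
        "gene": gene,
        "edited_alleles": n,
        "frameshift_n": n_fs, "frameshift_pct": pct(n_fs, n),
        "ge15bp_indel_n": n_large, "ge15bp_indel_pct": pct(n_large, n),
        "significant_n": n_sig, "significant_pct": pct(n_sig, n),
        "less_significant_n": n_less, "less_significant_pct": pct(n_less, n),
    }])
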