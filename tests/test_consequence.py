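"""Protein-consequence classification against an independent oracle."""

import numpy as np
import pytest

from rootedit.consequence import (SIG_FRAMESHIFT, SIG_LARGE_INDEL, SIG_LESS,
                                  classify_consequence, consequence_table)
from rootedit.events import (DELETION, INSERTION, SUBSTITUTION, EditEvent,
                             apply_events, normalize_events)
from rootedit.examples import _span_del

# hand-written codon table: the oracle never goes through Biopython
_BASES = "TCAG"
_AAS = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG")
CODON = {a + b + c: _AAS[i * 16 + j * 4 + k]
         for i, a in enumerate(_BASES)
         for j, b in enumerate(_BASES)
         for k, c in enumerate(_BASES)}


def oracle_consequence(events, locus):
    """Independent reimplementation for a single-segment CDS: apply events
    to the amplicon, locate the shifted CDS start/end, translate with a
    codon dict."""
    (s, e), = locus.cds_segments
    mutant = apply_events(locus.amplicon, sorted(events, key=lambda x: x.start))
    shift_before = sum(ev.net for ev in events if ev.end <= s)
    net_inside = sum(ev.net for ev in events if ev.start >= s and ev.end <= e)

    def translate(seq):
        prot = []
        for i in range(0, len(seq) - 2, 3):
            prot.append(CODON[seq[i:i + 3]])
        return "".join(prot)

    wt_prot = translate(locus.amplicon[s:])
    mut_prot = translate(mutant[s + shift_before:])

    def stop(p):
        i = p.find("*")
        return i if i >= 0 else len(p)

    return {
        "frameshift": net_inside % 3 != 0,
        "premature_stop": stop(mut_prot) < stop(wt_prot),
        "aa_changed": mut_prot[:stop(mut_prot)] != wt_prot[:stop(wt_prot)],
    }


def _random_cds_events(locus, rng):
    (s, e), = locus.cds_segments
    events = []
    n = int(rng.integers(1, 3))
    lo, hi = s + 10, e - 120
    positions = sorted(rng.choice(np.arange(lo, hi), size=n, replace=False))
    for i, pos in enumerate(positions):
        pos = int(pos)
        kind = rng.choice([DELETION, INSERTION, SUBSTITUTION])
        size = int(rng.integers(1, 30))
        if kind == DELETION:
            ev = EditEvent(start=pos, kind=DELETION, ref_span=size)
        elif kind == INSERTION:
            bases = "".join(rng.choice(list("ACGT"), size=size))
            ev = EditEvent(start=pos, kind=INSERTION, ref_span=0,
                           alt_seq=bases)
        else:
            run = min(size, 3)
            alt = "".join(
                rng.choice([b for b in "ACGT" if b != locus.amplicon[pos + k]])
                for k in range(run))
            ev = EditEvent(start=pos, kind=SUBSTITUTION, ref_span=run,
                           alt_seq=alt)
        if events and ev.start < events[-1].end + 4:
            continue
        events.append(ev)
    return events


def test_translation_agrees_with_codon_oracle(ccr1_locus):
    """100 random CDS mutants: frameshift / premature stop / aa change
    agree with a hand-rolled codon-table oracle."""
    rng = np.random.default_rng(17)
    checked = 0
    while checked < 100:
        events = _random_cds_events(ccr1_locus, rng)
        if not events:
            continue
        got = classify_consequence(tuple(events), ccr1_locus)
        want = oracle_consequence(events, ccr1_locus)
        assert got.frameshift == want["frameshift"]
        assert got.premature_stop == want["premature_stop"]
        assert got.aa_changed == want["aa_changed"]
        checked += 1


def test_large_spanning_deletion_is_frameshift_with_stop(ccr1_locus):
    ev = _span_del(ccr1_locus, 82)
    c = classify_consequence((ev,), ccr1_locus)
    assert c.frameshift and c.premature_stop
    assert c.significance == SIG_FRAMESHIFT


def test_inframe_3bp_deletion_less_significant(ccr1_locus):
    cut = ccr1_locus.guides[0].cut_pos
    ev = EditEvent(start=cut - 1, kind=DELETION, ref_span=3)
    c = classify_consequence((ev,), ccr1_locus)
    assert not c.frameshift
    assert c.aa_changed
    assert c.significance == SIG_LESS


def test_synonymous_substitution_leaves_protein_unchanged(ccr1_locus):
    """A wobble-position substitution that keeps the amino acid gives
    aa_changed = False."""
    (s, e), = ccr1_locus.cds_segments
    amp = ccr1_locus.amplicon
    target = None
    for pos in range(s, e - 3, 3):
        codon = amp[pos:pos + 3]
        for alt in "ACGT":
            if alt != codon[2] and CODON[codon[:2] + alt] == CODON[codon]:
                target = (pos + 2, alt)
                break
        if target:
            break
    pos, alt = target
    ev = EditEvent(start=pos, kind=SUBSTITUTION, ref_span=1, alt_seq=alt)
    c = classify_consequence((ev,), ccr1_locus)
    assert not c.aa_changed and not c.frameshift
    assert c.significance == SIG_LESS


def test_fifteen_bp_indel_is_significant_without_frameshift(ccr1_locus):
    """Exactly 15 bp sits in the significant class of the protein-level
    table even though the spectrum size classes call it small."""
    cut = ccr1_locus.guides[1].cut_pos
    ev = EditEvent(start=cut - 7, kind=DELETION, ref_span=15)
    c = classify_consequence((ev,), ccr1_locus)
    assert not c.frameshift and c.large_indel
    assert c.significance == SIG_LARGE_INDEL
    assert ev.size_class == "small"


def test_event_past_amplicon_fatal(ccr1_locus):
    ev = EditEvent(start=len(ccr1_locus.amplicon) - 2, kind=DELETION,
                   ref_span=10)
    with pytest.raises(ValueError, match="past the amplicon"):
        classify_consequence((ev,), ccr1_locus)


def test_dropout_only_cohort_all_frameshift(ccr1_locus):
    """64-bp dropouts (64 mod 3 = 1) shift the frame in every allele."""
    ev = EditEvent(start=ccr1_locus.guides[0].cut_pos, kind=DELETION,
                   ref_span=64)
    cons = [classify_consequence((ev,), ccr1_locus) for _ in range(10)]
    table = consequence_table(cons)
    assert table.loc[0, "frameshift_pct"] == 100.0


def test_percentages_sum_to_hundred(ccr1_locus, rng):
    events = [
        (EditEvent(start=ccr1_locus.guides[0].cut_pos, kind=DELETION,
                   ref_span=k),)
        for k in range(1, 12)
    ]
    cons = [classify_consequence(ev, ccr1_locus) for ev in events]
    t = consequence_table(cons)
    total = t.loc[0, "significant_pct"] + t.loc[0, "less_significant_pct"]
    assert abs(total - 100.0) <= 0.1


def test_empty_allele_set_gives_empty_table():
    t = consequence_table([])
    assert t.loc[0, "edited_alleles"] == 0
    assert t.loc[0, "frameshift_pct"] == 0.0
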