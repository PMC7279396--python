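"""Two-allele decoding of degenerate direct-sequencing consensus strings.

Direct Sanger sequencing of a mixed diploid amplicon yields a single
trace: where the two alleles agree the base is plain, where they disagree
the superposed peaks read as IUPAC ambiguity codes, and after a
heterozygous indel the two frame-shifted traces stay superposed to the
end.  This module inverts that superposition: it searches for a pair of
alleles — each the wild-type amplicon carrying at most one indel anchored
near a guide cut site (or spanning both), or substitution runs inside the
guide windows — whose superposition reproduces the consensus end to end.

Positions requiring three or more superposed bases indicate more than two
alleles (a chimera) and are rejected as undecodable, matching the known
failure mode of trace-decoding tools on chimeric transformants.  Pairs in
which both alleles carry insertions are outside the search space and come
back undecodable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._util import SET_FOR_IUPAC, revcomp
from .editcall import PlantCall, align_read, extract_events, reconstruct_read
from .locus import TargetLocus
from .simulate import make_degenerate

DEFAULT_MAX_SHIFT = 120
HOMOPOLYMER_SLACK = 12  # bp of placement slack around the first ambiguity
MAX_SUB_RUN = 15
MAX_SUB_TOTAL = 30

DECODED = "decoded"
UNDECODABLE = "undecodable"


@dataclass
class DecodeResult:
    status: str
    alleleA: str | None = None
    alleleB: str | None = None
    reason: str = ""
    events: tuple = ()            # (eventsA, eventsB) once decoded
    concordance: str = "not_compared"


def _sets(consensus: str):
    try:
        return [SET_FOR_IUPAC[c] for c in consensus]
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in consensus: {exc}") from exc


def _resolve(code_set: frozenset, base: str) -> str | None:
    """The partner base implied by a code given one allele's base."""
    if base not in code_set:
        return None
    if len(code_set) == 1:
        return base
    (other,) = code_set - {base}
    return other


def _anchor_positions(locus: TargetLocus, size: int, max_shift: int) -> list[int]:
    """Candidate deletion start positions for a deletion of ``size``."""
    c1, c2 = locus.cut_positions
    starts: set[int] = set()
    for g in locus.guides:
        lo, hi = g.attribution_window()
        for s in range(max(0, lo - size), hi + 1):
            # keep only placements whose interval touches the window
            if s <= hi and s + size > lo and s + size <= len(locus.amplicon):
                starts.add(s)
    return sorted(starts)


def _anchored(locus: TargetLocus, start: int, end: int) -> bool:
    c1, c2 = locus.cut_positions
    if start <= c1 and end >= c2:
        return True
    for g in locus.guides:
        lo, hi = g.attribution_window()
        if start <= hi and end >= lo:
            return True
    return False


def _verify(a: str, b: str, consensus: str) -> bool:
    return make_degenerate(a, b) == consensus


def decode_degenerate(
    consensus: str,
    locus: TargetLocus,
    max_shift: int = DEFAULT_MAX_SHIFT,
    orientation: str = "forward",
) -> DecodeResult:
    """Decode a degenerate consensus into its two constituent alleles.

    ``orientation='reverse'`` states that the trace was read with a
    reverse nested primer: the consensus is reverse-complemented into
    amplicon orientation before decoding.  ``max_shift`` bounds the indel
    sizes considered.  Returns a decoded pair (canonical order: the
    less-edited allele first) or an undecodable status with a reason.
    """
    if orientation == "reverse":
        consensus = revcomp(consensus.upper())
    consensus = consensus.upper()
    sets = _sets(consensus)
    if any(len(s) >= 3 for s in sets):
        return DecodeResult(UNDECODABLE, reason="chimeric")

    wt = locus.amplicon
    ambig = [i for i, s in enumerate(sets) if len(s) == 2]
    if not ambig:
        return _finish(consensus, consensus, locus)

    delta = len(consensus) - len(wt)
    if delta > max_shift or -delta > max_shift:
        return DecodeResult(UNDECODABLE, reason="shift beyond max_shift")

    pairs: set[tuple[str, str]] = set()
    if delta == 0:
        _candidates_wt_partner(consensus, sets, locus, max_shift, pairs)
    elif delta > 0:
        _candidates_insertion(consensus, sets, locus, delta, pairs)
    else:
        _candidates_double_deletion(consensus, sets, locus, -delta,
                                    max_shift, pairs)

    verified = {p for p in pairs if _verify(p[0], p[1], consensus)}
    if not verified:
        return DecodeResult(UNDECODABLE, reason="no consistent allele pair")
    if len(verified) > 1:
        return DecodeResult(UNDECODABLE,
                            reason=f"ambiguous ({len(verified)} candidate pairs)")
    a, b = verified.pop()
    return _finish(a, b, locus)


def _finish(a: str, b: str, locus: TargetLocus) -> DecodeResult:
    wt = locus.amplicon

    def n_events(seq: str) -> int:
        if seq == wt:
            return 0
        ra = align_read(seq, locus)
        kept, noise = extract_events(ra, locus, noise_filter=False)
        return len(kept)

    ordered = sorted((a, b), key=lambda s: (n_events(s), s))
    events = []
    for seq in ordered:
        if seq == wt:
            events.append(())
        else:
            kept, _ = extract_events(align_read(seq, locus), locus)
            events.append(kept)
    return DecodeResult(DECODED, alleleA=ordered[0], alleleB=ordered[1],
                        events=tuple(events))


def _candidates_wt_partner(consensus, sets, locus, max_shift, pairs) -> None:
    """Equal-length case: one allele is WT; the other has a deletion or subs."""
    wt = locus.amplicon
    p0 = next(i for i, s in enumerate(sets) if len(s) == 2)

    # substitution-only partner
    partner = []
    ok = True
    for i, s in enumerate(sets):
        base = _resolve(s, wt[i])
        if base is None:
            ok = False
            break
        partner.append(base)
    if ok:
        a = "".join(partner)
        diffs = [i for i in range(len(wt)) if a[i] != wt[i]]
        if diffs and len(diffs) <= MAX_SUB_TOTAL and all(
            _anchored(locus, i, i + 1) for i in diffs
        ):
            runs = _run_lengths(diffs)
            if max(runs) <= MAX_SUB_RUN:
                pairs.add((wt, a))

    # single-deletion partner: the deletion start is pinned to the first
    # ambiguity up to homopolymer slack
    for q in range(max(0, p0 - HOMOPOLYMER_SLACK), p0 + 1):
        for d in range(1, max_shift + 1):
            if q + d > len(wt):
                break
            if not _anchored(locus, q, q + d):
                continue
            # cheap prefilter before building the candidate string
            if wt[q + d : q + d + 6] != _expected_after(sets, wt, q, 6):
                continue
            a = wt[:q] + wt[q + d :]
            pairs.add(tuple(sorted((wt, a))))


def _expected_after(sets, wt, q, n):
    """Partner bases implied by the consensus at positions q..q+n-1."""
    out = []
    for i in range(q, min(q + n, len(wt), len(sets))):
        b = _resolve(sets[i], wt[i])
        if b is None:
            return None
        out.append(b)
    return "".join(out)


def _candidates_insertion(consensus, sets, locus, delta, pairs) -> None:
    """Longer-than-WT case: WT plus a partner carrying one insertion."""
    wt = locus.amplicon
    partner = []
    for i, s in enumerate(sets):
        if i < len(wt):
            base = _resolve(s, wt[i])
        else:
            base = next(iter(s)) if len(s) == 1 else None
        if base is None:
            return
        partner.append(base)
    b = "".join(partner)
    m = next((i for i in range(len(wt)) if b[i] != wt[i]), len(wt))
    for q in range(max(0, m - HOMOPOLYMER_SLACK), m + 1):
        if b[q + delta :] == wt[q:] and _anchored(locus, q, q + 1):
            pairs.add((wt, b))
            return


def _candidates_double_deletion(consensus, sets, locus, dmin,
                                max_shift, pairs) -> None:
    """Shorter-than-WT case: both alleles deleted; the smaller loss is dmin."""
    wt = locus.amplicon
    Lc = len(consensus)
    for s1 in _anchor_positions(locus, dmin, max_shift):
        if s1 + dmin > len(wt):
            continue
        b = wt[:s1] + wt[s1 + dmin :]
        # partner implied by the consensus against this candidate
        partner = []
        ok = True
        for i, cs in enumerate(sets):
            base = _resolve(cs, b[i])
            if base is None:
                ok = False
                break
            partner.append(base)
        if not ok:
            continue
        abar = "".join(partner)
        m = next((i for i in range(Lc) if abar[i] != wt[i]), None)
        if m is None:
            continue
        for q in range(max(0, m - HOMOPOLYMER_SLACK), m + 1):
            for d2 in range(dmin, max_shift + 1):
                if q + d2 > len(wt):
                    break
                if not _anchored(locus, q, q + d2):
                    continue
                if wt[q + d2 : q + d2 + 6] != abar[q : q + 6]:
                    continue
                a = wt[:q] + wt[q + d2 :]
                pairs.add(tuple(sorted((a, b))))


def _run_lengths(positions: list[int]) -> list[int]:
    runs = [1]
    for prev, cur in zip(positions, positions[1:]):
        if cur == prev + 1:
            runs[-1] += 1
        else:
            runs.append(1)
    return runs


# --- method comparison -----------------------------------------------------


def compare_methods(
    decode_results: dict[str, DecodeResult],
    plant_calls: dict[str, PlantCall],
    locus: TargetLocus,
) -> tuple[pd.DataFrame, Counter]:
    """Reconcile decoded allele pairs with subcloning-derived alleles.

    Per plant the outcome is ``same`` (identical allele sets),
    ``partial`` (overlapping but unequal), ``different`` (disjoint) or
    ``not_compared`` (undecodable trace).
    """
    rows = []
    summary: Counter = Counter()
    for plant_id, dr in decode_results.items():
        if plant_id not in plant_calls:
            raise KeyError(f"no subcloning calls for plant {plant_id}")
        pc = plant_calls[plant_id]
        sub_set = {reconstruct_read(a, locus) for a in pc.alleles}
        if dr.status != DECODED:
            outcome = "not_compared"
        else:
            dec_set = {dr.alleleA, dr.alleleB}
            if dec_set == sub_set:
                outcome = "same"
            elif dec_set & sub_set:
                outcome = "partial"
            else:
                outcome = "different"
        summary[outcome] += 1
        rows.append({
            "plant_id": plant_id,
            "decode_status": dr.status,
            "decode_reason": dr.reason,
            "n_subcloning_alleles": len(pc.alleles),
            "concordance": outcome,
        })
    return pd.DataFrame(rows), summary
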