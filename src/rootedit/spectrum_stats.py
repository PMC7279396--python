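"""Editing-rate and mutation-spectrum tabulation from allele calls.

Two related summaries are produced:

* per-subclone editing rates: the fraction of sequenced subclones that
  carry an edit, their per-guide attribution, and the fraction carrying
  the expected inter-guide large deletion;
* per-allele mutation spectra: membership counts per size-class x kind x
  guide bin, distinct edition types, and the prevalent edition types.

Guide columns use inclusion semantics: the sg1 column counts members
touching the sgRNA1 window including those that also touch sgRNA2, and
the sg1&2 column counts members touching both, so per-kind totals follow
inclusion-exclusion (total = sg1 + sg2 - sg1&2).  Guide percentages use
edited subclones (or edited alleles) as the denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from ._util import pct
from .events import DELETION, INSERTION, SUBSTITUTION, EditEvent
from .editcall import AlleleCall

KINDS = (DELETION, INSERTION, SUBSTITUTION)
SIZE_CLASSES = ("small", "large")


def _touches(events, label: str) -> bool:
    return any(e.guide_hit in (label, "both") for e in events)


def editing_rates(read_events: list[tuple[EditEvent, ...]],
                  gene: str = "gene") -> pd.DataFrame:
    """Subclone-level editing rates for one gene.

    ``read_events`` holds the guide-attributed events of every sequenced
    subclone (empty tuple = unedited subclone).
    """
    total = len(read_events)
    if total == 0:
        raise ValueError("no subclones to tabulate")
    edited = [ev for ev in read_events if ev]
    n_edited = len(edited)
    n_sg1 = sum(1 for ev in edited if _touches(ev, "sg1"))
    n_sg2 = sum(1 for ev in edited if _touches(ev, "sg2"))
    n_both = sum(1 for ev in edited
                 if _touches(ev, "sg1") and _touches(ev, "sg2"))
    n_dropout = sum(1 for ev in edited if any(e.inter_guide_dropout for e in ev))
    return pd.DataFrame([{
        "gene": gene,
        "total_subclones": total,
        "edited_subclones": n_edited,
        "edited_pct": pct(n_edited, total),
        "sg1_n": n_sg1, "sg1_pct": pct(n_sg1, n_edited),
        "sg2_n": n_sg2, "sg2_pct": pct(n_sg2, n_edited),
        "sg1and2_n": n_both, "sg1and2_pct": pct(n_both, n_edited),
        "large_deletion_n": n_dropout,
        "large_deletion_pct": pct(n_dropout, n_edited),
    }])


@dataclass
class SpectrumTable:
    gene: str
    n_edited: int
    n_types: int
    cells: dict           # (size_class, kind) -> {"sg1": n, "sg2": n, "sg1and2": n}
    kind_totals: dict     # (size_class, kind) -> n alleles
    any_kind: dict        # kind -> n alleles with any event of that kind
    n_dropout: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sc in SIZE_CLASSES:
            for kind in KINDS:
                cell = self.cells[(sc, kind)]
                n_tot = self.kind_totals[(sc, kind)]
                rows.append({
                    "gene": self.gene, "size_class": sc, "kind": kind,
                    "sg1": cell["sg1"], "sg2": cell["sg2"],
                    "sg1and2": cell["sg1and2"],
                    "total": n_tot, "total_pct": pct(n_tot, self.n_edited),
                })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out = {
            "gene": self.gene,
            "edited_alleles": self.n_edited,
            "edition_types": self.n_types,
            "expected_large_deletion_n": self.n_dropout,
            "expected_large_deletion_pct": pct(self.n_dropout, self.n_edited),
        }
        for kind in KINDS:
            out[f"{kind}_n"] = self.any_kind[kind]
            out[f"{kind}_pct"] = pct(self.any_kind[kind], self.n_edited)
        return out


def mutation_spectrum(alleles: list[AlleleCall], gene: str = "gene") -> SpectrumTable:
    """Per-allele mutation-spectrum memberships.

    An allele with several event kinds increments several categories, so
    category percentages may sum above 100.  ``edition_types`` counts the
    unique normalized event lists among edited alleles.
    """
    edited = [a for a in alleles if a.edited]
    cells = {(sc, k): {"sg1": 0, "sg2": 0, "sg1and2": 0}
             for sc in SIZE_CLASSES for k in KINDS}
    kind_totals = {(sc, k): 0 for sc in SIZE_CLASSES for k in KINDS}
    any_kind = {k: 0 for k in KINDS}
    n_dropout = 0
    for a in edited:
        if any(e.inter_guide_dropout for e in a.events):
            n_dropout += 1
        for kind in KINDS:
            if any(e.kind == kind for e in a.events):
                any_kind[kind] += 1
            for sc in SIZE_CLASSES:
                evs = [e for e in a.events
                       if e.kind == kind and e.size_class == sc]
                if not evs:
                    continue
                kind_totals[(sc, kind)] += 1
                t1 = _touches(evs, "sg1")
                t2 = _touches(evs, "sg2")
                if t1:
                    cells[(sc, kind)]["sg1"] += 1
                if t2:
                    cells[(sc, kind)]["sg2"] += 1
                if t1 and t2:
                    cells[(sc, kind)]["sg1and2"] += 1
    n_types = len({a.signature for a in edited})
    return SpectrumTable(gene=gene, n_edited=len(edited), n_types=n_types,
                         cells=cells, kind_totals=kind_totals,
                         any_kind=any_kind, n_dropout=n_dropout)


def _type_label(events: tuple[EditEvent, ...]) -> str:
    return "; ".join(e.signature() for e in events)


def prevalent_types(alleles: list[AlleleCall], k: int = 2) -> pd.DataFrame:
    """Top-k edition types with per-allele counts and whole percentages.

    Edition types are keyed by the normalized event signature; ties break
    toward the smaller total event size, then the leftmost position, so
    the ordering is deterministic.
    """
    edited = [a for a in alleles if a.edited]
    counter: Counter = Counter(a.signature for a in edited)
    by_sig = {a.signature: a.events for a in edited}

    def sort_key(sig):
        events = by_sig[sig]
        return (-counter[sig], sum(e.size for e in events),
                min(e.start for e in events), sig)

    top = sorted(counter, key=sort_key)[:k]
    rows = []
    for sig in top:
        n = counter[sig]
        rows.append({
            "type": _type_label(by_sig[sig]),
            "n_alleles": n,
            "pct": pct(n, len(edited), ndigits=0),
        })
    return pd.DataFrame(rows)
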