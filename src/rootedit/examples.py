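"""Demonstration loci and reference fixture cohorts.

Two synthetic demonstration loci mirror the geometry of the two target
genes of the worked example: a CCR1-like locus with its guide cuts 64 bp
apart and an IAA9A-like locus with a 54-bp spacing, both with two sense
guides inside a single CDS.  The fixture builders construct subclone read
sets whose per-category compositions reproduce the published editing-rate,
genotype, consequence and mutation-spectrum tables for those two genes, so
the whole reporting stack can be exercised end-to-end against known
printed percentages.

Everything here is synthetic: the amplicons are generated sequences, not
the real genes.
"""

from __future__ import annotations

import numpy as np

from .events import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    EditEvent,
    apply_events,
)
from .locus import TargetLocus, build_locus

GENE_PRESETS = {
    "CCR1": {"spacing": 64, "seed": 11},
    "IAA9A": {"spacing": 54, "seed": 13},
}

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS]


def demo_locus(
    gene: str = "CCR1",
    length: int = 600,
    cds: tuple[int, int] = (90, 540),
    cut1: int = 197,
    strands: tuple[str, str] = ("sense", "sense"),
    window: int = 10,
) -> TargetLocus:
    """Deterministically build a demonstration locus for one gene preset.

    The amplicon is drawn from a seeded generator, the CDS is stop-free in
    frame until its final codon, and NGG PAMs are planted so that both
    protospacers anchor uniquely with cut positions ``spacing`` bp apart.
    """
    preset = GENE_PRESETS[gene]
    spacing = preset["spacing"]
    cut2 = cut1 + spacing
    for attempt in range(50):
        rng = np.random.default_rng(preset["seed"] + 1000 * attempt)
        amp = _candidate_amplicon(rng, length, cds)
        cfg_guides = []
        ok = True
        for i, (cut, strand) in enumerate(zip((cut1, cut2), strands)):
            if strand == "sense":
                s = cut - 17
                amp = amp[: s + 20] + "CGG" + amp[s + 23 :]
                proto = amp[s : s + 20]
            else:
                s = cut - 3
                amp = amp[: s - 3] + "CC" + amp[s - 1 : ]
                from ._util import revcomp
                proto = revcomp(amp[s : s + 20])
            cfg_guides.append({"name": f"sg{i + 1}", "protospacer": proto,
                               "strand": strand})
        if _has_inframe_stop(amp, cds):
            continue
        config = {"name": gene, "window": window, "cds": [list(cds)],
                  "phase": 0, "guides": cfg_guides}
        try:
            locus = build_locus(amp, config)
        except Exception:
            continue  # e.g. a protospacer that happens to recur
        if locus.inter_guide_span == spacing:
            return locus
    raise RuntimeError(f"could not construct a demo locus for {gene}")


def _candidate_amplicon(rng, length, cds) -> str:
    bases = list(rng.choice(list("ACGT"), size=length))
    s, e = cds
    n_codons = (e - s) // 3
    coding = [ _CODONS[int(k)] for k in rng.integers(0, len(_CODONS),
                                                     size=n_codons - 1) ]
    coding.append("TGA")
    bases[s:e] = list("".join(coding))
    return "".join(bases)


def _has_inframe_stop(amp: str, cds) -> bool:
    s, e = cds
    for i in range(s, e - 3, 3):
        if amp[i : i + 3] in _STOPS:
            return True
    return False


# ---------------------------------------------------------------------------
# event placement helpers (reference coordinates, pre-normalization)


def _span_del(locus: TargetLocus, size: int) -> EditEvent:
    c1, c2 = locus.cut_positions
    extra = size - locus.inter_guide_span
    if extra < 0:
        raise ValueError("spanning deletion smaller than the guide spacing")
    start = c1 - extra // 2
    return EditEvent(start=start, kind=DELETION, ref_span=size)


def _del_at(cut: int, size: int) -> EditEvent:
    return EditEvent(start=cut - size // 2, kind=DELETION, ref_span=size)


def _ins_at(pos: int, size: int) -> EditEvent:
    bases = ("ACTGGTCAAC" * 4)[:size]
    return EditEvent(start=pos, kind=INSERTION, ref_span=0, alt_seq=bases)


def _sub_at(locus: TargetLocus, start: int, run: int) -> EditEvent:
    alt = "".join("T" if b != "T" else "G"
                  for b in locus.amplicon[start : start + run])
    return EditEvent(start=start, kind=SUBSTITUTION, ref_span=run, alt_seq=alt)


def _realize(locus: TargetLocus, groups) -> list[str]:
    """Expand (count, [events]) specs into mutant read sequences."""
    reads = []
    for count, events in groups:
        seq = apply_events(locus.amplicon, events)
        reads.extend([seq] * count)
    return reads


# ---------------------------------------------------------------------------
# mutation-spectrum fixtures (allele-level compositions per gene)


def spectrum_fixture_reads(gene: str, locus: TargetLocus) -> list[str]:
    """One read per edited allele, matching the per-category composition
    of the gene's published mutation-spectrum and consequence rows."""
    c1, c2 = locus.cut_positions
    if gene == "CCR1":
        groups = [
            # inter-guide dropouts (large deletions spanning both cuts)
            (14, [_span_del(locus, 82)]),
            (1, [_span_del(locus, 70)]),
            (1, [_span_del(locus, 77)]),
            (1, [_span_del(locus, 85)]),
            (1, [_span_del(locus, 91)]),
            (1, [_span_del(locus, 66)]),
            # large deletions at sgRNA2 only
            (1, [_del_at(c2, 20)]),
            (1, [_del_at(c2, 22)]),
            # small deletions at sgRNA1 only
            (2, [_del_at(c1, 2)]),
            (2, [_del_at(c1, 4)]),
            (2, [_del_at(c1, 6)]),
            (1, [_del_at(c1, 9)]),
            (3, [_del_at(c1, 5), _sub_at(locus, c2 - 1, 2)]),
            (2, [_del_at(c1, 7), _sub_at(locus, c2 - 1, 2)]),
            # small deletions at sgRNA2 only
            (11, [_del_at(c2, 1)]),
            (4, [_del_at(c2, 2), _sub_at(locus, c1 - 1, 2)]),
            (4, [_del_at(c2, 4), _sub_at(locus, c1 - 1, 2)]),
            (4, [_del_at(c2, 3), _sub_at(locus, c1 - 1, 2)]),
            (1, [_del_at(c2, 15)]),
            (2, [_del_at(c2, 2)]),
            (2, [_del_at(c2, 4)]),
            (2, [_del_at(c2, 5)]),
            (2, [_del_at(c2, 7)]),
            (1, [_del_at(c2, 8)]),
            (1, [_del_at(c2, 10)]),
            (2, [_del_at(c2, 6)]),
            (2, [_del_at(c2, 9)]),
            (2, [_del_at(c2, 12)]),
            # small insertions
            (2, [_ins_at(c1, 1)]),
            (1, [_ins_at(c1, 6)]),
            (1, [_ins_at(c2, 3)]),
            # standalone substitution runs at sgRNA1
        ] + [
            (1, [_sub_at(locus, c1 + off, run)])
            for off, run in ((-8, 1), (-6, 1), (-4, 1), (-2, 1), (0, 1),
                             (2, 1), (4, 1), (6, 1), (8, 1),
                             (-7, 2), (-3, 2), (1, 3))
        ]
    elif gene == "IAA9A":
        groups = [
            (26, [_span_del(locus, 73)]),
            (1, [_span_del(locus, 60)]),
            # large deletion at sgRNA1 only, alone and with a small
            # insertion at sgRNA2
            (1, [EditEvent(start=c1 - 10, kind=DELETION, ref_span=19)]),
            (4, [EditEvent(start=c1 - 10, kind=DELETION, ref_span=19),
                 _ins_at(c2, 2)]),
            (3, [EditEvent(start=c1 - 10, kind=DELETION, ref_span=19),
                 _ins_at(c2, 3)]),
            (3, [EditEvent(start=c1 - 10, kind=DELETION, ref_span=19),
                 _ins_at(c2, 5)]),
            (1, [_ins_at(c2, 4)]),
            # paired small deletions at both guides
            (7, [_del_at(c1, 3), _del_at(c2, 4)]),
            (7, [_del_at(c1, 3), _del_at(c2, 3), _sub_at(locus, c1 - 9, 2)]),
            (5, [_del_at(c1, 3), _del_at(c2, 6), _sub_at(locus, c1 - 9, 2)]),
            # small deletions at sgRNA1 only
            (3, [_del_at(c1, 5)]),
            (2, [_del_at(c1, 5), _sub_at(locus, c2 - 8, 2)]),
            (5, [_del_at(c1, 6), _ins_at(c1 + 8, 2)]),
            # small deletions at sgRNA2 only
            (8, [_del_at(c2, 1)]),
            # large insertion at sgRNA1 with a small deletion at sgRNA2
            (2, [_ins_at(c1, 16), _del_at(c2, 2)]),
            (2, [_ins_at(c1, 17), _del_at(c2, 1)]),
            (2, [_ins_at(c1, 18), _del_at(c2, 2)]),
            (2, [_ins_at(c1, 19), _del_at(c2, 2)]),
            (2, [_ins_at(c1, 20), _del_at(c2, 1)]),
            (2, [_ins_at(c1, 22), _del_at(c2, 3)]),
        ]
    else:
        raise ValueError(f"unknown gene {gene!r}")
    return _realize(locus, groups)


# ---------------------------------------------------------------------------
# editing-rate fixtures (subclone-level compositions, Table-2 shaped)


def rate_fixture_reads(gene: str, locus: TargetLocus) -> list[str]:
    """Subclone reads matching the gene's editing-frequency composition."""
    c1, c2 = locus.cut_positions
    wt = locus.amplicon
    if gene == "CCR1":
        span, n_wt, n_sg1, n_sg2, n_double = 82, 189, 24, 43, 3
    elif gene == "IAA9A":
        span, n_wt, n_sg1, n_sg2, n_double = 73, 7, 9, 4, 48
    else:
        raise ValueError(f"unknown gene {gene!r}")
    n_span = {"CCR1": 19, "IAA9A": 27}[gene]
    groups = [
        (n_wt, []),
        (n_sg1, [_del_at(c1, 2)]),
        (n_sg2, [_del_at(c2, 3)]),
        (n_span, [_span_del(locus, span)]),
        (n_double, [_del_at(c1, 2), _del_at(c2, 3)]),
    ]
    return _realize(locus, groups)


# ---------------------------------------------------------------------------
# genotype fixtures (plant-level compositions, Table-1 shaped)


def genotype_fixture_plants(
    gene: str, locus: TargetLocus, reads_per_allele: int = 3
) -> list[tuple[str, list[tuple[str, str]]]]:
    """Per-plant subclone read sets matching the gene's genotype counts.

    Subclones are replicated deterministically per allele so that every
    allele of every plant is observed; class recovery under random
    subclone sampling is exercised elsewhere.
    """
    c1, c2 = locus.cut_positions
    wt = locus.amplicon

    def edited(i: int) -> str:
        # a bank of distinct edited alleles: alternate guides, vary size
        cut = c1 if i % 2 == 0 else c2
        size = 1 + (i % 14)
        ev = _del_at(cut, size)
        if i >= 28:
            ev = _span_del(locus, locus.inter_guide_span + 2 + i % 10)
        return apply_events(wt, [ev])

    plants: list[tuple[str, list[str]]] = []
    k = 0
    if gene == "CCR1":
        for j in range(10):
            plants.append((f"CCR1_mono_{j + 1}", [wt, edited(k)])); k += 1
        for j in range(13):
            plants.append((f"CCR1_chimWT_{j + 1}",
                           [wt, edited(k), edited(k + 1)])); k += 2
        plants.append(("CCR1_chimAll_1", [edited(k + i) for i in range(7)]))
    elif gene == "IAA9A":
        for j in range(7):
            plants.append((f"IAA9A_bi_{j + 1}", [edited(k), edited(k + 1)]))
            k += 2
        for j in range(4):
            plants.append((f"IAA9A_chimAll_{j + 1}",
                           [edited(k), edited(k + 1), edited(k + 2)])); k += 3
        plants.append(("IAA9A_mono_1", [wt, edited(k)])); k += 1
        plants.append(("IAA9A_wt_1", [wt]))
    else:
        raise ValueError(f"unknown gene {gene!r}")

    out = []
    for pid, alleles in plants:
        reads = [(f"{pid}_r{i + 1}", seq)
                 for i, seq in enumerate(
                     s for s in alleles for _ in range(reads_per_allele))]
        out.append((pid, reads))
    return out


# ---------------------------------------------------------------------------
# end-to-end drivers: fixture reads -> full pipeline -> report tables


def run_gene_tables(gene: str) -> dict:
    """Run the complete genotyping pipeline on the gene's fixture cohorts.

    Returns the four report tables (genotype classes, editing rates,
    protein consequences, mutation spectrum plus prevalent types), each
    computed from raw fixture reads through alignment, event extraction,
    collapsing and classification.
    """
    from .consequence import classify_consequence, consequence_table
    from .editcall import AlleleCall, call_plant
    from .genotype import classify_plant, genotype_table
    from .spectrum_stats import editing_rates, mutation_spectrum, prevalent_types

    locus = demo_locus(gene)

    genotypes = []
    for pid, reads in genotype_fixture_plants(gene, locus):
        pc = call_plant(reads, locus, plant_id=pid)
        genotypes.append(classify_plant(pc.alleles, plant_id=pid))
    genotype_tbl = genotype_table(genotypes, gene=gene)

    rate_reads = [(f"s{i}", s)
                  for i, s in enumerate(rate_fixture_reads(gene, locus))]
    rate_calls = call_plant(rate_reads, locus)
    rate_tbl = editing_rates([rc.events for rc in rate_calls.reads], gene=gene)

    spec_reads = [(f"a{i}", s)
                  for i, s in enumerate(spectrum_fixture_reads(gene, locus))]
    spec_calls = call_plant(spec_reads, locus)
    # one allele record per sequenced edited allele (alleles are counted
    # per plant in the source tables, so duplicates stay separate)
    alleles = [AlleleCall(f"a{i}", rc.events, 1, bool(rc.events))
               for i, rc in enumerate(spec_calls.reads)]
    spectrum_tbl = mutation_spectrum(alleles, gene=gene)
    consequences = [classify_consequence(a.events, locus)
                    for a in alleles if a.edited]
    return {
        "locus": locus,
        "genotype": genotype_tbl,
        "rates": rate_tbl,
        "consequence": consequence_table(consequences, gene=gene),
        "spectrum": spectrum_tbl,
        "prevalent": prevalent_types(alleles, k=2),
    }
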