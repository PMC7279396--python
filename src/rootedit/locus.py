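"""Target-locus model: amplicon, CDS geometry and the two guide sites.

The locus provides the reference coordinate frame used by every other
module.  Coordinates are 0-based half-open internally; report writers
convert to 1-based closed.  The Cas9 cut is modelled as the canonical
SpCas9 blunt cut 3 bp 5' of the PAM on the protospacer strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml
from Bio import SeqIO

from ._util import revcomp

PROTOSPACER_LEN = 20
PAM_LEN = 3
CUT_OFFSET = 3  # bp 5' of the PAM, on the protospacer strand

DEFAULT_WINDOW = 10  # edit-attribution half-width around the cut, bp


class LocusError(ValueError):
    """Raised for invalid locus configuration or unanchorable guides."""


@dataclass(frozen=True)
class GuideSite:
    """One registered sgRNA site on the amplicon.

    ``start`` is the leftmost amplicon coordinate of the protospacer match
    (on the amplicon's own strand); ``cut_pos`` is the coordinate of the
    phosphodiester bond that Cas9 cuts, i.e. the cut falls between
    ``cut_pos - 1`` and ``cut_pos``.
    """

    name: str
    protospacer: str
    strand: str  # 'sense' | 'antisense'
    pam: str
    start: int
    cut_pos: int
    window: int = DEFAULT_WINDOW

    def protospacer_interval(self) -> tuple[int, int]:
        """Protospacer + PAM interval on the amplicon (half-open)."""
        if self.strand == "sense":
            return (self.start, self.start + PROTOSPACER_LEN + PAM_LEN)
        return (self.start - PAM_LEN, self.start + PROTOSPACER_LEN)

    def attribution_window(self) -> tuple[int, int]:
        """Closed interval of coordinates attributed to this guide."""
        return (self.cut_pos - self.window, self.cut_pos + self.window)


@dataclass(frozen=True)
class Variant:
    """A known SNP in amplicon coordinates (used for guide validation)."""

    pos: int
    ref_base: str
    alt_base: str


@dataclass
class TargetLocus:
    name: str
    amplicon: str
    cds_segments: list[tuple[int, int]]
    cds_phase: int
    guides: tuple[GuideSite, GuideSite]

    def __post_init__(self) -> None:
        self.amplicon = self.amplicon.upper()
        if len(self.guides) != 2:
            raise LocusError("a locus carries exactly two guide sites")
        self.guides = tuple(sorted(self.guides, key=lambda g: g.cut_pos))
        prev = 0
        for s, e in self.cds_segments:
            if not (0 <= s < e <= len(self.amplicon)):
                raise LocusError(f"CDS segment ({s},{e}) outside amplicon")
            if s < prev:
                raise LocusError("CDS segments must be ordered, non-overlapping")
            prev = e
        if sum(e - s for s, e in self.cds_segments) < 3:
            raise LocusError("total CDS length must be >= 3")
        if self.inter_guide_span <= 0:
            raise LocusError("guide cut positions must be distinct")

    @property
    def sg1(self) -> GuideSite:
        return self.guides[0]

    @property
    def sg2(self) -> GuideSite:
        return self.guides[1]

    @property
    def cut_positions(self) -> tuple[int, int]:
        return (self.guides[0].cut_pos, self.guides[1].cut_pos)

    @property
    def inter_guide_span(self) -> int:
        return self.guides[1].cut_pos - self.guides[0].cut_pos


def anchor_guide(
    amplicon: str,
    name: str,
    protospacer: str,
    strand: str,
    window: int = DEFAULT_WINDOW,
    cut_pos: int | None = None,
) -> GuideSite:
    """Locate a protospacer on the amplicon and derive PAM and cut position.

    The protospacer must occur exactly once on the stated strand and be
    followed (3' on that strand) by an NGG PAM.  ``cut_pos`` may be given
    explicitly to override the blunt-cut convention.
    """
    amplicon = amplicon.upper()
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise LocusError(f"guide {name}: protospacer must be {PROTOSPACER_LEN} nt")
    if strand not in ("sense", "antisense"):
        raise LocusError(f"guide {name}: strand must be sense/antisense")

    query = protospacer if strand == "sense" else revcomp(protospacer)
    hits = [m.start() for m in re.finditer(f"(?={re.escape(query)})", amplicon)]
    if len(hits) != 1:
        raise LocusError(
            f"guide not anchored: {name} found {len(hits)} times on {strand} strand"
        )
    start = hits[0]

    if strand == "sense":
        pam = amplicon[start + PROTOSPACER_LEN : start + PROTOSPACER_LEN + PAM_LEN]
        derived_cut = start + PROTOSPACER_LEN - CUT_OFFSET
    else:
        # PAM is 3' of the protospacer on the antisense strand, i.e. the
        # 3 bp immediately left of the match on the amplicon.
        pam_on_amplicon = amplicon[max(start - PAM_LEN, 0) : start]
        pam = revcomp(pam_on_amplicon)
        derived_cut = start + CUT_OFFSET
    if len(pam) != PAM_LEN or not re.fullmatch("[ACGT]GG", pam):
        raise LocusError(f"guide {name}: PAM {pam!r} does not match NGG")

    cut = derived_cut if cut_pos is None else cut_pos
    if not (0 < cut < len(amplicon)):
        raise LocusError(f"guide {name}: cut position {cut} outside amplicon")
    if window < 1:
        raise LocusError(f"guide {name}: window must be >= 1")
    return GuideSite(name=name, protospacer=protospacer, strand=strand,
                     pam=pam, start=start, cut_pos=cut, window=window)


def load_locus(fasta_path, config) -> TargetLocus:
    """Build a validated :class:`TargetLocus` from a FASTA and a config.

    ``config`` is a mapping or a path to a YAML file with keys ``name``,
    ``window`` (optional), ``cds`` (list of [start, end]), ``phase`` and
    ``guides`` (two entries with name/protospacer/strand and an optional
    explicit ``cut_pos``).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise LocusError(f"expected a single-record FASTA, got {len(records)}")
    amplicon = str(records[0].seq).upper()

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    return build_locus(amplicon, config)


def build_locus(amplicon: str, config: dict) -> TargetLocus:
    window = int(config.get("window", DEFAULT_WINDOW))
    guide_specs = config.get("guides", [])
    if len(guide_specs) != 2:
        raise LocusError("config must name exactly two guides")
    guides = tuple(
        anchor_guide(
            amplicon,
            name=g.get("name", f"sg{i + 1}"),
            protospacer=g["protospacer"],
            strand=g.get("strand", "sense"),
            window=int(g.get("window", window)),
            cut_pos=g.get("cut_pos"),
        )
        for i, g in enumerate(guide_specs)
    )
    return TargetLocus(
        name=config.get("name", "locus"),
        amplicon=amplicon,
        cds_segments=[tuple(seg) for seg in config.get("cds", [[0, len(amplicon)]])],
        cds_phase=int(config.get("phase", 0)),
        guides=guides,
    )


def flag_guide_snps(locus: TargetLocus, variants: list[Variant]) -> dict[str, dict]:
    """Flag guides whose protospacer or PAM overlaps a known variant.

    A flagged guide is annotated as potentially ineffective on the variant
    haplotype, since target-site polymorphism can abolish Cas9 recognition.
    """
    for v in variants:
        if not (0 <= v.pos < len(locus.amplicon)):
            raise LocusError(f"variant position {v.pos} outside amplicon")
        if locus.amplicon[v.pos] != v.ref_base.upper():
            raise LocusError(
                f"variant ref mismatch at {v.pos}: "
                f"amplicon has {locus.amplicon[v.pos]}, variant says {v.ref_base}"
            )
    report: dict[str, dict] = {}
    for g in locus.guides:
        lo, hi = g.protospacer_interval()
        hits = [v for v in variants if lo <= v.pos < hi]
        report[g.name] = {
            "flagged": bool(hits),
            "variants": hits,
            "note": ("editing may be ineffective on the variant haplotype"
                     if hits else ""),
        }
    return report
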