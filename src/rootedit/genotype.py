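"""Plant-level genotype classification over the diploid taxonomy.

A diploid transformant's subclone-derived allele inventory maps onto six
classes: WT/WT, homozygous (one edited allele on both chromosomes),
biallelic (two distinct edited alleles), monoallelic (one edited + WT),
and the two chimera classes (>= 3 distinct alleles, with or without a
remaining WT allele).  A plant is a putative knock-out when no WT allele
remains and a putative knock-down when a WT allele persists alongside
edited ones.

Homozygous vs under-sampled biallelic/monoallelic cannot be decided from
subclones alone; a single edited allele is only confirmed homozygous when
its subclone support reaches ``homozygote_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import pct
from .editcall import AlleleCall

G_CLASSES = ("WT_WT", "homozygous", "biallelic", "monoallelic",
             "chimera_all_edited", "chimera_with_WT")

KO = "putative_knock_out"
KD = "putative_knock_down"
WT_STATUS = "wild_type"

DEFAULT_HOMOZYGOTE_MIN = 5


@dataclass
class PlantGenotype:
    plant_id: str
    n_distinct_alleles: int
    has_WT: bool
    g_class: str
    ko_status: str
    homozygous_unconfirmed: bool = False


def classify_plant(
    alleles: list[AlleleCall],
    homozygote_min: int = DEFAULT_HOMOZYGOTE_MIN,
    plant_id: str = "plant",
) -> PlantGenotype:
    """Deterministically map an allele inventory to its genotype class."""
    if not alleles:
        raise ValueError(f"no subclones for plant {plant_id}")
    if homozygote_min < 2:
        raise ValueError("homozygote_min must be >= 2 subclones")
    edited = [a for a in alleles if a.edited]
    has_wt = any(not a.edited for a in alleles)
    n = len(alleles)
    unconfirmed = False

    if n >= 3:
        g_class = "chimera_with_WT" if has_wt else "chimera_all_edited"
    elif n == 2:
        g_class = "monoallelic" if has_wt else "biallelic"
    else:  # n == 1
        if has_wt:
            g_class = "WT_WT"
        else:
            g_class = "homozygous"
            unconfirmed = edited[0].support < homozygote_min

    if edited and not has_wt:
        ko = KO
    elif edited:
        ko = KD
    else:
        ko = WT_STATUS
    return PlantGenotype(plant_id=plant_id, n_distinct_alleles=n,
                         has_WT=has_wt, g_class=g_class, ko_status=ko,
                         homozygous_unconfirmed=unconfirmed)


def genotype_table(plants: list[PlantGenotype],
                   gene: str = "gene") -> pd.DataFrame:
    """Cohort summary: per-class counts and percentages.

    Two percentage views are emitted because both are in common use:
    ``pct_total`` over all transgenic plants and ``pct_edited`` over the
    edited plants only.  Percentages are rounded half-up to one decimal.
    """
    total = len(plants)
    edited_plants = [p for p in plants if p.ko_status != WT_STATUS]
    n_edited = len(edited_plants)
    rows = []
    for cls in G_CLASSES:
        k = sum(1 for p in plants if p.g_class == cls)
        rows.append({
            "gene": gene, "class": cls, "n": k,
            "pct_total": pct(k, total),
            "pct_edited": pct(k, n_edited),
        })
    rows.append({
        "gene": gene, "class": "edited_plants", "n": n_edited,
        "pct_total": pct(n_edited, total), "pct_edited": 100.0 if n_edited else 0.0,
    })
    for status in (KO, KD):
        k = sum(1 for p in plants if p.ko_status == status)
        rows.append({
            "gene": gene, "class": status, "n": k,
            "pct_total": pct(k, total), "pct_edited": pct(k, n_edited),
        })
    return pd.DataFrame(rows)
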