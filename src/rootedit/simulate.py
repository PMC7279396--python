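"""Synthetic-data generation with known ground truth.

Everything the pipeline consumes can be produced here: Cas9 editing
outcomes at the two guide sites of a locus (small/large deletions,
insertions, substitution runs and the inter-guide dropout expected from a
dual-guide design), plant allele compositions over the diploid genotype
taxonomy, multinomial subclone sampling, degenerate direct-sequencing
consensus strings, and two-group FTIR-like spectra with planted
discriminant bands.

All randomness flows from one ``numpy.random.Generator``; per-plant
streams are split with ``Generator.spawn`` so cohort outputs do not depend
on plant order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import DNA, IUPAC_FOR_SET
from .events import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    EditEvent,
    apply_events,
    normalize_events,
)
from .ftir import SpectraSet
from .locus import TargetLocus

PLANT_CLASSES = (
    "WT_WT",
    "homozygous",
    "biallelic",
    "monoallelic",
    "chimera_all_edited",
    "chimera_with_WT",
)

SMALL_GEOM_P = 0.5
SMALL_MAX_SIZE = 15
LARGE_SIZE_RANGE = (16, 100)  # uniform, inclusive
SUB_RUN_RANGE = (1, 3)        # substitution runs are short mismatch runs


@dataclass(frozen=True)
class EditParams:
    """Per-outcome probabilities for one simulated repair event.

    ``p_dropout`` is the per-allele probability of a single deletion
    spanning both cut sites; the per-guide outcome probabilities apply to
    each guide independently when no dropout occurs, and must sum to <= 1
    (the remainder is "no edit at this guide").  Defaults reflect a
    deletion-dominated NHEJ outcome mix with the inter-guide dropout at a
    substantial minority of alleles, as seen in dual-guide designs.
    """

    p_small_del: float = 0.30
    p_large_del: float = 0.10
    p_small_ins: float = 0.08
    p_large_ins: float = 0.02
    p_sub: float = 0.15
    p_dropout: float = 0.25
    dropout_jitter: int = 3  # max extra bp deleted on each flank

    def __post_init__(self) -> None:
        per_guide = (self.p_small_del + self.p_large_del + self.p_small_ins
                     + self.p_large_ins + self.p_sub)
        probs = (self.p_small_del, self.p_large_del, self.p_small_ins,
                 self.p_large_ins, self.p_sub, self.p_dropout)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if per_guide > 1.0 + 1e-12:
            raise ValueError("per-guide outcome probabilities must sum to <= 1")

    @property
    def p_guide_edit(self) -> float:
        return (self.p_small_del + self.p_large_del + self.p_small_ins
                + self.p_large_ins + self.p_sub)


@dataclass
class TruthRecord:
    """Planted ground truth for one simulated plant."""

    plant_id: str
    intended_class: str
    alleles: list[str]                       # distinct allele sequences
    events: list[tuple[EditEvent, ...]]      # per allele, normalized


@dataclass
class SimRead:
    read_id: str
    sequence: str
    allele_index: int


def _small_size(rng: np.random.Generator) -> int:
    """Geometric(p=0.5) truncated to [1, 15]."""
    while True:
        s = int(rng.geometric(SMALL_GEOM_P))
        if s <= SMALL_MAX_SIZE:
            return s


def _large_size(rng: np.random.Generator) -> int:
    lo, hi = LARGE_SIZE_RANGE
    return int(rng.integers(lo, hi + 1))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n))


def _sub_run(reference: str, start: int, length: int,
             rng: np.random.Generator) -> str:
    """Replacement bases, each guaranteed to differ from the reference."""
    out = []
    for i in range(length):
        ref = reference[start + i]
        out.append(rng.choice([b for b in DNA if b != ref]))
    return "".join(out)


def _guide_event(locus: TargetLocus, cut: int, params: EditParams,
                 rng: np.random.Generator) -> EditEvent | None:
    outcomes = ("small_del", "large_del", "small_ins", "large_ins", "sub", "none")
    probs = np.array([params.p_small_del, params.p_large_del, params.p_small_ins,
                      params.p_large_ins, params.p_sub,
                      1.0 - params.p_guide_edit])
    choice = rng.choice(len(outcomes), p=probs / probs.sum())
    kind = outcomes[choice]
    L = len(locus.amplicon)
    if kind == "none":
        return None
    if kind.endswith("del"):
        size = _small_size(rng) if kind == "small_del" else _large_size(rng)
        start = max(0, min(cut - size // 2, L - size))
        return EditEvent(start=start, kind=DELETION, ref_span=size)
    if kind.endswith("ins"):
        size = _small_size(rng) if kind == "small_ins" else _large_size(rng)
        return EditEvent(start=cut, kind=INSERTION, ref_span=0,
                         alt_seq=_random_bases(rng, size))
    run = int(rng.integers(SUB_RUN_RANGE[0], SUB_RUN_RANGE[1] + 1))
    start = max(0, min(cut - 1, L - run))
    return EditEvent(start=start, kind=SUBSTITUTION, ref_span=run,
                     alt_seq=_sub_run(locus.amplicon, start, run, rng))


def simulate_allele(
    locus: TargetLocus, params: EditParams, rng: np.random.Generator
) -> tuple[str, tuple[EditEvent, ...]]:
    """Simulate one repaired allele; returns (sequence, truth events).

    The truth events are returned left-aligned in reference coordinates.
    Degenerate parameters (all probabilities zero) give back the unedited
    amplicon with an empty truth.
    """
    c1, c2 = locus.cut_positions
    events: list[EditEvent] = []
    if rng.random() < params.p_dropout:
        a = int(rng.integers(0, params.dropout_jitter + 1))
        b = int(rng.integers(0, params.dropout_jitter + 1))
        start = max(0, c1 - a)
        end = min(len(locus.amplicon), c2 + b)
        events.append(EditEvent(start=start, kind=DELETION, ref_span=end - start))
    else:
        for cut in (c1, c2):
            ev = _guide_event(locus, cut, params, rng)
            if ev is None:
                continue
            if any(not (ev.end <= p.start or ev.start >= p.end) for p in events):
                continue  # a large event from guide 1 already covers this site
            events.append(ev)
    truth = normalize_events(events, locus)
    return apply_events(locus.amplicon, truth), truth


def simulate_plant(
    locus: TargetLocus,
    class_spec: str,
    params: EditParams,
    rng: np.random.Generator,
    plant_id: str = "plant",
    n_chimera_alleles: int = 3,
    max_retries: int = 200,
) -> TruthRecord:
    """Simulate a plant's allele inventory realizing one genotype class.

    ``n_chimera_alleles`` is the total number of distinct alleles for the
    two chimera classes (including the WT allele for ``chimera_with_WT``);
    it must be >= 3.  Distinctness of edited alleles is enforced by
    resampling; an unreachable class (e.g. any edited class under
    zero-probability parameters) raises after bounded retries.
    """
    if class_spec not in PLANT_CLASSES:
        raise ValueError(f"unknown class_spec {class_spec!r}")
    if class_spec.startswith("chimera") and n_chimera_alleles < 3:
        raise ValueError("chimera classes need >= 3 alleles")

    n_edited = {
        "WT_WT": 0,
        "homozygous": 1,
        "biallelic": 2,
        "monoallelic": 1,
        "chimera_all_edited": n_chimera_alleles,
        "chimera_with_WT": n_chimera_alleles - 1,
    }[class_spec]
    with_wt = class_spec in ("WT_WT", "monoallelic", "chimera_with_WT")

    alleles: list[str] = []
    truths: list[tuple[EditEvent, ...]] = []
    if with_wt:
        alleles.append(locus.amplicon)
        truths.append(())
    tries = 0
    while sum(1 for t in truths if t) < n_edited:
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"class {class_spec} unreachable under the given parameters"
            )
        seq, truth = simulate_allele(locus, params, rng)
        if not truth or seq in alleles:
            continue
        alleles.append(seq)
        truths.append(truth)
    return TruthRecord(plant_id=plant_id, intended_class=class_spec,
                       alleles=alleles, events=truths)


def sample_subclones(
    alleles: list[str],
    n: int,
    rng: np.random.Generator,
    weights: list[float] | None = None,
    noise: float = 0.0,
    locus: TargetLocus | None = None,
    prefix: str = "sub",
) -> list[SimRead]:
    """Draw ``n`` subclone reads from an allele set.

    Reads are drawn with the stated weights (uniform by default).  With
    ``noise`` > 0 each base is substituted with that probability; when a
    locus is supplied, noise is injected only outside the guide
    attribution windows so truth attribution stays unambiguous.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.full(len(alleles), 1.0 / len(alleles)) if weights is None else (
        np.asarray(weights, dtype=float) / np.sum(weights))
    picks = rng.choice(len(alleles), size=n, p=w)
    reads = []
    for i, k in enumerate(picks):
        seq = alleles[int(k)]
        if noise > 0.0:
            seq = _inject_noise(seq, noise, rng, locus)
        reads.append(SimRead(read_id=f"{prefix}{i + 1}", sequence=seq,
                             allele_index=int(k)))
    return reads


def _inject_noise(seq: str, rate: float, rng: np.random.Generator,
                  locus: TargetLocus | None) -> str:
    protected: list[tuple[int, int]] = []
    if locus is not None:
        # windows are in reference coordinates; for reads that differ in
        # length, a generous pad keeps the edited region untouched
        pad = 8
        for g in locus.guides:
            lo, hi = g.attribution_window()
            protected.append((lo - pad, hi + pad))
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if any(lo <= i <= hi for lo, hi in protected):
            continue
        out[i] = rng.choice([b for b in DNA if b != out[i]])
    return "".join(out)


def make_degenerate(*alleles: str) -> str:
    """Position-wise superposition of allele sequences (IUPAC codes).

    Both (or all) traces are anchored at the read start; each allele then
    walks its own coordinates, so after the first length-discordant event
    the superposition emulates the frame-shifted double trace of direct
    Sanger sequencing of a mixed amplicon.  Beyond the end of a shorter
    allele the remaining trace(s) read through alone.
    """
    if not alleles:
        raise ValueError("at least one allele required")
    length = max(len(a) for a in alleles)
    out = []
    for i in range(length):
        bases = frozenset(a[i] for a in alleles if i < len(a))
        out.append(IUPAC_FOR_SET[bases])
    return "".join(out)


# ---------------------------------------------------------------------------
# FTIR-like spectra


DEFAULT_GRID = (400.0, 4000.0, 4.0)

#: shared absorbance peaks (center cm^-1, sigma cm^-1, amplitude) roughly
#: emulating a plant cell-wall fingerprint plus CH/OH stretch regions
SHARED_PEAKS = (
    (1035.0, 20.0, 1.0),
    (1160.0, 15.0, 0.45),
    (1240.0, 18.0, 0.35),
    (1370.0, 15.0, 0.30),
    (1510.0, 10.0, 0.35),
    (1595.0, 14.0, 0.40),
    (1650.0, 20.0, 0.30),
    (1738.0, 12.0, 0.25),
    (2920.0, 40.0, 0.40),
    (3350.0, 120.0, 0.60),
)

DEFAULT_PLANTED_BANDS = ((1510.0, 12.0, 1.0), (1595.0, 14.0, -1.0),
                         (1120.0, 12.0, 1.0))


def simulate_spectra(
    rng: np.random.Generator,
    grid: np.ndarray | None = None,
    n_per_group: tuple[int, int] = (10, 10),
    group_names: tuple[str, str] = ("control", "edited"),
    planted_bands: tuple[tuple[float, float, float], ...] = DEFAULT_PLANTED_BANDS,
    effect_scale: float = 5.0,
    noise_sd: float = 0.004,
    baseline_order: int = 2,
    baseline_scale: float = 0.05,
    peak_jitter: float = 0.0,
) -> tuple[SpectraSet, list[dict]]:
    """Two-group synthetic spectra with planted discriminant bands.

    Each spectrum is a smooth random polynomial baseline + shared Gaussian
    peaks (with mild per-sample amplitude jitter) + group-specific
    amplitude shifts at the planted bands + white noise.  A planted band
    is (center cm^-1, width sigma cm^-1, signed unit effect); its actual
    amplitude is ``effect * effect_scale * noise_sd``.  Returns the
    spectra and the ground-truth band list.
    """
    if grid is None:
        lo, hi, step = DEFAULT_GRID
        grid = np.arange(lo, hi + step / 2, step)
    grid = np.asarray(grid, dtype=float)
    for center, _, _ in planted_bands:
        if not (grid[0] <= center <= grid[-1]):
            raise ValueError(f"planted band {center} outside the grid")

    n0, n1 = n_per_group
    rows, labels, ids = [], [], []
    for gi, (gname, n) in enumerate(zip(group_names, (n0, n1))):
        for si in range(n):
            x = np.zeros_like(grid)
            t = (grid - grid[0]) / (grid[-1] - grid[0])
            coeffs = rng.normal(0.0, baseline_scale, size=baseline_order + 1)
            x += np.polyval(coeffs, t) + 2 * baseline_scale
            for center, sigma, amp in SHARED_PEAKS:
                a = amp * (1.0 + rng.normal(0.0, peak_jitter))
                x += a * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
            if gi == 1:
                for center, sigma, effect in planted_bands:
                    a = effect * effect_scale * noise_sd
                    x += a * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
            x += rng.normal(0.0, noise_sd, size=grid.size)
            rows.append(x)
            labels.append(gname)
            ids.append(f"{gname}_{si + 1}")
    truth = [
        {"center": c, "sigma": s,
         "direction": "higher" if e > 0 else "lower",
         "amplitude": e * effect_scale * noise_sd}
        for c, s, e in planted_bands
    ]
    spectra = SpectraSet(wavenumbers=grid, absorbance=np.array(rows),
                         labels=list(labels), sample_ids=ids)
    return spectra, truth


# ---------------------------------------------------------------------------
# cohorts


DEFAULT_CLASS_MIX = {
    "WT_WT": 0.05,
    "homozygous": 0.05,
    "biallelic": 0.20,
    "monoallelic": 0.30,
    "chimera_all_edited": 0.15,
    "chimera_with_WT": 0.25,
}


@dataclass
class SimulatedPlant:
    truth: TruthRecord
    reads: list[SimRead]


def simulate_cohort(
    locus: TargetLocus,
    n_plants: int,
    rng: np.random.Generator,
    class_mix: dict[str, float] | None = None,
    n_subclones: int = 15,
    params: EditParams | None = None,
    noise: float = 0.0,
    n_chimera_alleles: int = 3,
) -> list[SimulatedPlant]:
    """Simulate a cohort of plants with subclone reads.

    Plant classes are drawn from ``class_mix``; each plant gets its own
    spawned random stream keyed by order, so results are reproducible and
    independent of downstream consumption order.
    """
    mix = class_mix or DEFAULT_CLASS_MIX
    classes = list(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    params = params or EditParams()
    plant_rngs = rng.spawn(n_plants)
    cohort = []
    for i, prng in enumerate(plant_rngs):
        cls = classes[int(prng.choice(len(classes), p=probs))]
        pid = f"plant_{i + 1:03d}"
        truth = simulate_plant(locus, cls, params, prng, plant_id=pid,
                               n_chimera_alleles=n_chimera_alleles)
        reads = sample_subclones(truth.alleles, n_subclones, prng,
                                 noise=noise, locus=locus,
                                 prefix=f"{pid}_")
        cohort.append(SimulatedPlant(truth=truth, reads=reads))
    return cohort
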