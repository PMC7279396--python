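"""Synthetic-data generator: editing outcomes, sampling, superposition."""

import numpy as np
import pytest

from rootedit._util import SET_FOR_IUPAC
from rootedit.events import DELETION, INSERTION
from rootedit.simulate import (DEFAULT_CLASS_MIX, EditParams, make_degenerate,
                               sample_subclones, simulate_allele,
                               simulate_cohort, simulate_plant,
                               simulate_spectra)

ZERO = EditParams(p_small_del=0, p_large_del=0, p_small_ins=0,
                  p_large_ins=0, p_sub=0, p_dropout=0)


def test_zero_params_give_unedited_allele(ccr1_locus, rng):
    seq, truth = simulate_allele(ccr1_locus, ZERO, rng)
    assert seq == ccr1_locus.amplicon
    assert truth == ()


def test_dropout_only_zero_jitter_deletes_exact_span(ccr1_locus, rng):
    """Pure inter-guide dropout with no jitter removes exactly the
    inter-cut interval."""
    params = EditParams(p_small_del=0, p_large_del=0, p_small_ins=0,
                        p_large_ins=0, p_sub=0, p_dropout=1.0,
                        dropout_jitter=0)
    seq, truth = simulate_allele(ccr1_locus, params, rng)
    assert len(truth) == 1
    ev = truth[0]
    assert ev.kind == DELETION
    assert ev.size == ccr1_locus.inter_guide_span == 64
    assert ev.inter_guide_dropout
    assert len(seq) == len(ccr1_locus.amplicon) - 64


def test_length_bookkeeping(ccr1_locus, rng):
    """Edited length = amplicon - deletions + insertions, every allele."""
    params = EditParams()
    L = len(ccr1_locus.amplicon)
    for _ in range(300):
        seq, truth = simulate_allele(ccr1_locus, params, rng)
        net = sum(e.net for e in truth)
        assert len(seq) == L + net


def test_fixed_seed_reproducibility(ccr1_locus):
    def run():
        rng = np.random.default_rng(99)
        cohort = simulate_cohort(ccr1_locus, 10, rng, n_subclones=5)
        return [(p.truth.intended_class, tuple(r.sequence for r in p.reads))
                for p in cohort]

    assert run() == run()


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        EditParams(p_small_del=0.9, p_sub=0.5)
    with pytest.raises(ValueError):
        EditParams(p_dropout=-0.1)


class TestSimulatePlant:
    def test_wt_wt_single_wild_type_allele(self, ccr1_locus, rng):
        t = simulate_plant(ccr1_locus, "WT_WT", EditParams(), rng)
        assert t.alleles == [ccr1_locus.amplicon]

    def test_chimera_seven_distinct_edited_alleles(self, ccr1_locus, rng):
        t = simulate_plant(ccr1_locus, "chimera_all_edited", EditParams(),
                           rng, n_chimera_alleles=7)
        assert len(t.alleles) == 7
        assert len(set(t.alleles)) == 7
        assert ccr1_locus.amplicon not in t.alleles

    def test_monoallelic_one_edited_one_wt(self, ccr1_locus, rng):
        t = simulate_plant(ccr1_locus, "monoallelic", EditParams(), rng)
        assert len(t.alleles) == 2
        assert ccr1_locus.amplicon in t.alleles

    def test_unreachable_class_raises(self, ccr1_locus, rng):
        with pytest.raises(RuntimeError, match="unreachable"):
            simulate_plant(ccr1_locus, "biallelic", ZERO, rng, max_retries=10)


class TestSampleSubclones:
    def test_weighted_sampling_expectation(self, ccr1_locus, rng):
        """An 8:1 weighted biallelic plant yields ~8:1 subclone support."""
        alleles = ["A" * 100, "C" * 100]
        reads = sample_subclones(alleles, 9000, rng, weights=[8, 1])
        n_major = sum(1 for r in reads if r.allele_index == 0)
        # 3 binomial SD around 8/9
        p = 8 / 9
        sd = (9000 * p * (1 - p)) ** 0.5
        assert abs(n_major - 9000 * p) < 3 * sd

    def test_wt_plant_reads_identical_to_amplicon(self, ccr1_locus, rng):
        reads = sample_subclones([ccr1_locus.amplicon], 5, rng)
        assert all(r.sequence == ccr1_locus.amplicon for r in reads)

    def test_noise_rate_within_binomial_bounds(self, ccr1_locus, rng):
        noise = 0.01
        reads = sample_subclones([ccr1_locus.amplicon], 1000, rng,
                                 noise=noise, locus=ccr1_locus)
        protected = []
        pad = 8
        for g in ccr1_locus.guides:
            lo, hi = g.attribution_window()
            protected.append((lo - pad, hi + pad))
        eligible = [i for i in range(len(ccr1_locus.amplicon))
                    if not any(lo <= i <= hi for lo, hi in protected)]
        n_err = sum(
            1 for r in reads for i in eligible
            if r.sequence[i] != ccr1_locus.amplicon[i]
        )
        n_tot = len(reads) * len(eligible)
        sd = (n_tot * noise * (1 - noise)) ** 0.5
        assert abs(n_err - n_tot * noise) < 3 * sd
        # guide windows stay clean
        for r in reads[:50]:
            for lo, hi in protected:
                assert (r.sequence[lo:hi + 1]
                        == ccr1_locus.amplicon[lo:hi + 1])


class TestMakeDegenerate:
    def test_identical_alleles_no_ambiguity(self, ccr1_locus):
        cons = make_degenerate(ccr1_locus.amplicon, ccr1_locus.amplicon)
        assert cons == ccr1_locus.amplicon

    def test_positional_superposition_oracle(self, ccr1_locus):
        """WT + 1-bp deletion: clean prefix, ambiguity-bearing suffix,
        matching an independently coded position-wise superposition."""
        wt = ccr1_locus.amplicon
        cut = ccr1_locus.guides[0].cut_pos
        edited = wt[:cut] + wt[cut + 1:]
        cons = make_degenerate(wt, edited)
        # oracle: index-wise superposition
        expected = []
        for i in range(len(wt)):
            bases = {wt[i]} | ({edited[i]} if i < len(edited) else set())
            expected.append(
                next(c for c, s in SET_FOR_IUPAC.items()
                     if s == frozenset(bases)))
        assert cons == "".join(expected)
        assert cons[:cut] == wt[:cut]
        assert any(c not in "ACGT" for c in cons[cut:])

    def test_dropout_ambiguity_onset_at_upstream_cut(self, ccr1_locus):
        wt = ccr1_locus.amplicon
        c1, c2 = ccr1_locus.cut_positions
        edited = wt[:c1] + wt[c2:]
        cons = make_degenerate(wt, edited)
        first_ambig = next(i for i, c in enumerate(cons) if c not in "ACGT")
        assert c1 <= first_ambig <= c1 + 8  # within homopolymer slack


class TestSimulateSpectra:
    def test_default_grid_has_901_points(self, rng):
        ss, _ = simulate_spectra(rng)
        assert ss.wavenumbers.size == 901
        assert ss.wavenumbers[0] == 400.0 and ss.wavenumbers[-1] == 4000.0

    def test_planted_band_exceeds_three_pooled_se(self, rng):
        """With only white noise around the shared peaks, a planted band
        at 5x the noise SD clears 3x the pooled standard error."""
        ss, truth = simulate_spectra(rng, noise_sd=0.004, effect_scale=5.0,
                                     baseline_scale=0.0)
        grid = ss.wavenumbers
        for band in truth:
            j = int(np.argmin(np.abs(grid - band["center"])))
            a = ss.absorbance[[i for i, l in enumerate(ss.labels)
                               if l == "control"], j]
            b = ss.absorbance[[i for i, l in enumerate(ss.labels)
                               if l == "edited"], j]
            se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
            assert abs(b.mean() - a.mean()) > 3 * se

    def test_zero_effect_groups_differ_only_by_noise(self, rng):
        ss, _ = simulate_spectra(rng, effect_scale=0.0, noise_sd=0.004,
                                 baseline_scale=0.0)
        a = ss.absorbance[:10].mean(axis=0)
        b = ss.absorbance[10:].mean(axis=0)
        se = 0.004 * np.sqrt(2 / 10)
        assert np.max(np.abs(a - b)) < 6 * se

    def test_band_outside_grid_fatal(self, rng):
        with pytest.raises(ValueError, match="outside the grid"):
            simulate_spectra(rng, planted_bands=((5000.0, 10.0, 1.0),))


def test_cohort_class_frequencies_match_mixture(ccr1_locus):
    rng = np.random.default_rng(5)
    cohort = simulate_cohort(ccr1_locus, 400, rng, n_subclones=2)
    for cls, p in DEFAULT_CLASS_MIX.items():
        n = sum(1 for c in cohort if c.truth.intended_class == cls)
        sd = (400 * p * (1 - p)) ** 0.5
        assert abs(n - 400 * p) < 4 * sd, cls
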