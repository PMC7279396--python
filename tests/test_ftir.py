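"""Spectra preprocessing, NIPALS PLS-DA and discriminant-band selection."""

import numpy as np
import pytest

from rootedit.ftir import (SpectraSet, _rubberband_baseline,
                           average_replicates, explained_variance_summary,
                           fit_plsda, preprocess, select_bands)
from rootedit.simulate import simulate_spectra


def _grid():
    return np.arange(400.0, 4000.1, 4.0)


def _set(rows, labels):
    return SpectraSet(_grid(), np.asarray(rows), labels)


def test_flat_spectrum_zero_after_baseline_and_offset():
    ss = _set([np.full(901, 0.7)] * 4, ["a", "a", "b", "b"])
    out = preprocess(ss)
    assert np.allclose(out.absorbance, 0.0)


def test_all_zero_spectrum_fatal():
    ss = _set([np.zeros(901)] * 4, ["a", "a", "b", "b"])
    with pytest.raises(ValueError, match="degenerate spectrum"):
        preprocess(ss)


def test_rubberband_removes_linear_baseline_under_one_peak():
    """Known linear baseline + single Gaussian: residual baseline is
    below 1% of the peak height."""
    w = _grid()
    baseline = 0.2 + 0.0001 * w
    peak = 1.0 * np.exp(-0.5 * ((w - 1600.0) / 30.0) ** 2)
    spectrum = baseline + peak
    est = _rubberband_baseline(w, spectrum)
    resid = spectrum - est
    off_peak = np.abs(w - 1600.0) > 200.0
    assert np.max(np.abs(resid[off_peak])) < 0.01  # 1% of peak height
    assert abs(resid[np.argmin(np.abs(w - 1600.0))] - 1.0) < 0.02


def test_monotonicity_required():
    with pytest.raises(ValueError, match="monotone"):
        SpectraSet(np.array([1.0, 3.0, 2.0]), np.ones((1, 3)), ["a"])


def test_average_replicates_means_and_labels(rng):
    rows = rng.normal(size=(6, 901)) + 2.0
    ss = _set(list(rows), ["a"] * 3 + ["b"] * 3)
    means = average_replicates(ss, ["r1", "r1", "r1", "r2", "r2", "r2"])
    assert means.absorbance.shape == (2, 901)
    assert np.allclose(means.absorbance[0], rows[:3].mean(axis=0))
    assert means.labels == ["a", "b"]


def test_mixed_label_replicates_rejected(rng):
    ss = _set(list(rng.normal(size=(2, 901))), ["a", "b"])
    with pytest.raises(ValueError, match="mixes labels"):
        average_replicates(ss, ["r1", "r1"])


class TestFitPLSDA:
    def test_scores_orthogonal_and_variance_positive(self, rng):
        ss, _ = simulate_spectra(rng)
        m = fit_plsda(preprocess(ss), 3)
        T = m.scores
        for i in range(3):
            for j in range(i + 1, 3):
                dot = abs(T[:, i] @ T[:, j])
                assert dot < 1e-8 * np.linalg.norm(T[:, i]) * \
                    np.linalg.norm(T[:, j])
        assert np.all(m.explained_x_variance_pct > 0)
        assert m.explained_x_variance_pct.sum() <= 100.0 + 1e-9

    def test_strong_planted_band_separates_groups(self, rng):
        """One discriminant band at 10x the noise floor: component-1
        scores split the groups with zero overlap."""
        ss, _ = simulate_spectra(rng, planted_bands=((1510.0, 12.0, 1.0),),
                                 effect_scale=10.0, baseline_scale=0.0)
        m = fit_plsda(preprocess(ss), 2)
        t1 = m.scores[:, 0]
        g0 = t1[[i for i, l in enumerate(ss.labels) if l == "control"]]
        g1 = t1[[i for i, l in enumerate(ss.labels) if l == "edited"]]
        assert max(g0) < min(g1) or max(g1) < min(g0)

    def test_duplicated_columns_get_identical_loadings(self, rng):
        x = rng.normal(size=(8, 5))
        x[:, 4] = x[:, 2]
        ss = SpectraSet(np.arange(5, dtype=float), x, ["a"] * 4 + ["b"] * 4)
        m = fit_plsda(ss, 2)
        assert np.allclose(m.x_loadings[2], m.x_loadings[4])
        assert np.allclose(m.weights[2], m.weights[4])

    def test_agrees_with_reference_pls_implementation(self, rng):
        """Scores match scikit-learn's PLSRegression up to sign."""
        from sklearn.cross_decomposition import PLSRegression

        ss, _ = simulate_spectra(rng)
        pre = preprocess(ss)
        m = fit_plsda(pre, 2)
        X = pre.absorbance - pre.absorbance.mean(axis=0)
        Y = np.array([[1.0, 0.0] if l == "control" else [0.0, 1.0]
                      for l in pre.labels])
        Y = Y - Y.mean(axis=0)
        sk = PLSRegression(n_components=2, scale=False).fit(X, Y)
        for k in range(2):
            r = np.corrcoef(sk.x_scores_[:, k], m.scores[:, k])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-6

    def test_single_group_rejected(self, rng):
        ss = _set(list(rng.normal(size=(4, 901))), ["a"] * 4)
        with pytest.raises(ValueError, match="two groups"):
            fit_plsda(ss, 2)

    def test_sample_order_invariance(self, rng):
        ss, _ = simulate_spectra(rng)
        pre = preprocess(ss)
        order = rng.permutation(len(pre.labels))
        shuffled = SpectraSet(pre.wavenumbers, pre.absorbance[order],
                              [pre.labels[i] for i in order],
                              [pre.sample_ids[i] for i in order])
        m1 = fit_plsda(pre, 2)
        m2 = fit_plsda(shuffled, 2)
        assert np.allclose(np.abs(m1.x_loadings), np.abs(m2.x_loadings),
                           atol=1e-8)
        assert np.allclose(m1.explained_x_variance_pct,
                           m2.explained_x_variance_pct)


def test_permutation_null_separation_not_significant():
    """With no planted effect, the labeled separation of component-1
    scores sits inside its own permutation distribution."""
    rng = np.random.default_rng(2024)

    def separation(labels, pre):
        ss2 = SpectraSet(pre.wavenumbers, pre.absorbance, list(labels))
        m = fit_plsda(ss2, 1)
        t = m.scores[:, 0]
        a = t[[i for i, l in enumerate(labels) if l == "control"]]
        return abs(a.mean() - t.mean())

    ss, _ = simulate_spectra(rng, effect_scale=0.0)
    pre = preprocess(ss)
    observed = separation(pre.labels, pre)
    perms = []
    labels = np.array(pre.labels)
    for _ in range(100):
        perms.append(separation(rng.permutation(labels), pre))
    p = np.mean([x >= observed for x in perms])
    assert p > 0.05


def test_band_selection_recovers_planted_bands(rng):
    """Clean construction (no baseline variation): every planted band is
    recovered with the correct direction.  Recovery under full variance
    is asserted as a median over cohorts elsewhere."""
    ss, truth = simulate_spectra(rng, baseline_scale=0.0)
    pre = preprocess(ss)
    m = fit_plsda(pre, 2)
    bands = select_bands(m, pre)
    for t in truth:
        match = [b for b in bands if abs(b.wavenumber - t["center"]) <= 8]
        assert match, f"band at {t['center']} not recovered"
        # direction agrees with the planted sign (edited vs control)
        want = "edited" if t["direction"] == "higher" else "control"
        assert any(b.higher_in == want for b in match)


def test_band_annotation_covers_lignin_region(rng):
    ss, _ = simulate_spectra(rng, planted_bands=((1510.0, 10.0, 1.0),),
                             effect_scale=8.0, baseline_scale=0.0)
    pre = preprocess(ss)
    bands = select_bands(fit_plsda(pre, 2), pre)
    lignin = [b for b in bands if abs(b.wavenumber - 1510) <= 8]
    assert lignin and "lignin" in lignin[0].annotation


def test_explained_variance_summary_shape(rng):
    ss, _ = simulate_spectra(rng)
    m = fit_plsda(preprocess(ss), 2)
    s = explained_variance_summary(m)
    assert len(s["per_component_pct"]) == 2
    assert s["first_two_pct"] > 0
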