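"""FTIR spectra preprocessing, two-group PLS-DA and discriminant bands.

The discriminant analysis is an iterative (NIPALS) PLS2 fit of the
column-centered absorbance matrix against centered one-hot group
indicators, with X deflation after each component.  Loadings magnitudes on
the first two components mark the wavenumbers driving group separation;
contiguous selections are merged to their extremum and annotated from a
bundled band-assignment table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import round_half_up


@dataclass
class SpectraSet:
    """Labeled absorbance matrix on a monotone wavenumber grid."""

    wavenumbers: np.ndarray          # (p,), strictly monotone, cm^-1
    absorbance: np.ndarray           # (n, p)
    labels: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        if self.absorbance.shape != (len(self.labels), self.wavenumbers.size):
            raise ValueError("absorbance shape inconsistent with labels/grid")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(len(self.labels))]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def restrict(self, lo: float, hi: float) -> "SpectraSet":
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        return SpectraSet(self.wavenumbers[mask], self.absorbance[:, mask],
                          list(self.labels), list(self.sample_ids))


@dataclass
class DiscriminantBand:
    wavenumber: float
    component: int
    loading: float
    higher_in: str            # group with the higher median absorbance
    annotation: str = ""


@dataclass
class PLSDAModel:
    n_components: int
    scores: np.ndarray              # (n, k)
    x_loadings: np.ndarray          # (p, k)
    weights: np.ndarray             # (p, k)
    y_loadings: np.ndarray          # (g, k)
    explained_x_variance_pct: np.ndarray  # (k,)
    group_score_means: dict[str, np.ndarray]
    groups: list[str]
    wavenumbers: np.ndarray
    x_mean: np.ndarray


# --- preprocessing ---------------------------------------------------------


def _rubberband_baseline(w: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Lower convex hull of the spectrum, interpolated over the grid."""
    # Andrew's monotone chain, lower hull only; w is ascending here.
    pts = list(zip(w, a))
    hull: list[tuple[float, float]] = []
    for p in pts:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            if (x2 - x1) * (p[1] - y1) - (y2 - y1) * (p[0] - x1) <= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    hx = np.array([p[0] for p in hull])
    hy = np.array([p[1] for p in hull])
    return np.interp(w, hx, hy)


def _poly_baseline(w: np.ndarray, a: np.ndarray, order: int) -> np.ndarray:
    t = (w - w[0]) / (w[-1] - w[0])
    coeffs = np.polyfit(t, a, order)
    return np.polyval(coeffs, t)


def preprocess(
    spectra: SpectraSet,
    baseline: str = "rubberband",
    poly_order: int = 2,
    analysis_range: tuple[float, float] = (800.0, 4000.0),
) -> SpectraSet:
    """Baseline-correct, area-normalize and offset-correct each spectrum.

    The steps run per spectrum, in order: baseline subtraction (convex-hull
    rubberband by default, low-order polynomial as the alternative), unit-
    area normalization over the analysis range, and offset correction
    subtracting the per-spectrum minimum.  The output is restricted to the
    analysis range.
    """
    if not np.all(np.isfinite(spectra.absorbance)):
        raise ValueError("raw absorbance matrix must be finite")
    ss = spectra.restrict(*analysis_range)
    w = ss.wavenumbers
    ascending = w[0] < w[-1]
    wa = w if ascending else w[::-1]
    out = np.empty_like(ss.absorbance)
    for i, row in enumerate(ss.absorbance):
        if np.allclose(row, 0.0):
            raise ValueError(f"degenerate spectrum: {ss.sample_ids[i]} is all zero")
        r = row if ascending else row[::-1]
        if baseline == "rubberband":
            r = r - _rubberband_baseline(wa, r)
        elif baseline == "polynomial":
            r = r - _poly_baseline(wa, r, poly_order)
        elif baseline != "none":
            raise ValueError(f"unknown baseline method {baseline!r}")
        area = np.trapezoid(np.abs(r), wa)
        if area > 1e-12:
            r = r / area
        r = r - r.min()
        out[i] = r if ascending else r[::-1]
    return SpectraSet(w, out, list(ss.labels), list(ss.sample_ids))


def average_replicates(spectra: SpectraSet,
                       replicate_ids: list[str]) -> SpectraSet:
    """Mean spectrum per replicate group (analysis runs on these means)."""
    order: list[str] = []
    for rid in replicate_ids:
        if rid not in order:
            order.append(rid)
    rows, labels, ids = [], [], []
    for rid in order:
        idx = [i for i, r in enumerate(replicate_ids) if r == rid]
        labs = {spectra.labels[i] for i in idx}
        if len(labs) != 1:
            raise ValueError(f"replicate group {rid} mixes labels {labs}")
        rows.append(spectra.absorbance[idx].mean(axis=0))
        labels.append(labs.pop())
        ids.append(rid)
    return SpectraSet(spectra.wavenumbers, np.array(rows), labels, ids)


# --- PLS-DA ---------------------------------------------------------------


def fit_plsda(
    spectra: SpectraSet,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PLSDAModel:
    """NIPALS PLS2 of centered absorbance against one-hot group labels."""
    groups = spectra.groups
    if len(groups) < 2:
        raise ValueError("PLS-DA needs at least two groups")
    counts = {g: spectra.labels.count(g) for g in groups}
    if min(counts.values()) < 2:
        raise ValueError("each group needs at least 2 samples")
    n, p = spectra.absorbance.shape
    if n_components > min(n - 1, p):
        raise ValueError("too many components for the data size")

    x_mean = spectra.absorbance.mean(axis=0)
    X = spectra.absorbance - x_mean
    Y = np.zeros((n, len(groups)))
    for i, lab in enumerate(spectra.labels):
        Y[i, groups.index(lab)] = 1.0
    Y = Y - Y.mean(axis=0)

    ss_x0 = float(np.sum(X * X))
    T = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    explained = np.zeros(n_components)

    for k in range(n_components):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-15:
                raise RuntimeError(
                    f"NIPALS degenerate at component {k + 1}: zero weight vector"
                )
            w /= nw
            t = X @ w
            q = Y.T @ t / (t @ t)
            u = Y @ q / (q @ q)
            if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        else:
            raise RuntimeError(
                f"NIPALS did not converge for component {k + 1} "
                f"(max_iter={max_iter}, tol={tol:g}, "
                f"last delta={np.linalg.norm(t - t_old):g})"
            )
        pk = X.T @ t / (t @ t)
        X = X - np.outer(t, pk)
        Y = Y - np.outer(t, q)
        T[:, k], W[:, k], P[:, k], Q[:, k] = t, w, pk, q
        explained[k] = 100.0 * (t @ t) * (pk @ pk) / ss_x0

    means = {
        g: T[[i for i, lab in enumerate(spectra.labels) if lab == g]].mean(axis=0)
        for g in groups
    }
    return PLSDAModel(
        n_components=n_components, scores=T, x_loadings=P, weights=W,
        y_loadings=Q, explained_x_variance_pct=explained,
        group_score_means=means, groups=groups,
        wavenumbers=spectra.wavenumbers.copy(), x_mean=x_mean,
    )


# --- discriminant bands ----------------------------------------------------

#: coarse literature-derived assignments of cell-wall FTIR regions
BAND_ANNOTATIONS = (
    (890.0, 900.0, "cellulose anomeric C-H deformation"),
    (1000.0, 1180.0, "polysaccharide C-O / C-C stretch (cellulose, hemicellulose)"),
    (1200.0, 1280.0, "lignin G-ring breathing / C-O of acetyl (xylan)"),
    (1310.0, 1340.0, "cellulose CH2 wagging / lignin S-ring"),
    (1360.0, 1400.0, "C-H deformation in cellulose and hemicellulose"),
    (1420.0, 1470.0, "lignin aromatic skeletal + C-H deformation"),
    (1500.0, 1520.0, "lignin aromatic skeletal vibration"),
    (1580.0, 1615.0, "lignin aromatic ring stretch"),
    (1630.0, 1670.0, "absorbed water / conjugated C=O"),
    (1700.0, 1750.0, "C=O stretch of carboxyl/ester (hemicellulose, lignin)"),
    (2800.0, 3000.0, "C-H stretch (methyl/methylene)"),
    (3200.0, 3600.0, "O-H stretch (polysaccharide hydroxyl)"),
)


def _annotate_band(w: float) -> str:
    for lo, hi, text in BAND_ANNOTATIONS:
        if lo <= w <= hi:
            return text
    return ""


def select_bands(
    model: PLSDAModel,
    spectra: SpectraSet,
    threshold_quantile: float = 0.95,
    components: tuple[int, ...] = (1, 2),
) -> list[DiscriminantBand]:
    """Discriminant wavenumbers from loading magnitudes.

    For each requested component, wavenumbers whose absolute loading
    exceeds the ``threshold_quantile`` of that component's |loading|
    distribution are selected; contiguous grid runs are merged to their
    extremum.  The direction reports which group has the higher median
    absorbance at the band.
    """
    if len(model.groups) != 2:
        raise ValueError("band direction is defined for two groups")
    g0, g1 = model.groups
    med = {
        g: np.median(
            spectra.absorbance[
                [i for i, lab in enumerate(spectra.labels) if lab == g]
            ],
            axis=0,
        )
        for g in (g0, g1)
    }
    bands: list[DiscriminantBand] = []
    for comp in components:
        if not 1 <= comp <= model.n_components:
            raise ValueError(f"component {comp} not fitted")
        load = model.x_loadings[:, comp - 1]
        thr = np.quantile(np.abs(load), threshold_quantile)
        idx = np.nonzero(np.abs(load) >= thr)[0]
        if idx.size == 0:
            continue
        runs: list[list[int]] = [[int(idx[0])]]
        for i in idx[1:]:
            if int(i) == runs[-1][-1] + 1:
                runs[-1].append(int(i))
            else:
                runs.append([int(i)])
        for run in runs:
            peak = run[int(np.argmax(np.abs(load[run])))]
            w = float(model.wavenumbers[peak])
            diff = med[g1][peak] - med[g0][peak]
            bands.append(DiscriminantBand(
                wavenumber=w, component=comp, loading=float(load[peak]),
                higher_in=g1 if diff > 0 else g0,
                annotation=_annotate_band(w),
            ))
    bands.sort(key=lambda b: (b.component, b.wavenumber))
    return bands


def explained_variance_summary(model: PLSDAModel) -> dict:
    ev = [round_half_up(v, 1) for v in model.explained_x_variance_pct]
    return {
        "per_component_pct": ev,
        "first_two_pct": round_half_up(
            float(np.sum(model.explained_x_variance_pct[:2])), 1),
    }
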