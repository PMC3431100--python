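"""Dual-Gaussian histogram segmentation of breast CT into fat and gland.

The attenuation histogram of a skin-stripped breast CT is bimodal: a fat
(adipose) peak at lower mu and a fibroglandular peak at higher mu.  Each
histogram is fitted with the sum of two Gaussian components

    f(x) = A1 exp(-(x - B1)^2 / C1^2) + A2 exp(-(x - B2)^2 / C2^2)

(note the width convention: C = sqrt(2) * sigma), and voxels are assigned to
tissue classes by one of three thresholds:

``minimum``
    the interior minimum of the fitted sum between the two centroids,
    applied to the whole-breast (global) histogram;
``crosspoint``
    the attenuation where the two fitted components are equal (closed form
    via the log-quadratic), computed slice by slice;
``purity95``
    per-slice threshold pair such that the selected regions are at least
    95% one fitted tissue component (component-integral purity via the
    error function), falling back to the maximum attainable purity where
    the components overlap too much.

The per-slice variants exist because reconstructed attenuation values carry
a residual object-size dependence: a single global threshold mis-bins voxels
in slices whose equivalent radius differs from the breast average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.signal import find_peaks
from scipy.special import erf

from .grid import BreastMask, VoxelGrid

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.002  # cm^-1; resolves peaks ~0.03-0.08 cm^-1 apart
MIN_SLICE_VOXELS = 500


class ThresholdError(RuntimeError):
    """A threshold could not be derived from the fit (degenerate mixture)."""


@dataclass
class SliceHistogram:
    """Histogram of attenuation values for one slice or the whole breast."""

    bin_edges: np.ndarray
    counts: np.ndarray
    slice_index: int | str = "global"
    equivalent_radius_cm: float = float("nan")

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def build_histogram(values, bin_width: float = DEFAULT_BIN_WIDTH,
                    slice_index: int | str = "global",
                    equivalent_radius_cm: float = float("nan")
                    ) -> SliceHistogram:
    """Fixed-bin-width histogram over the breast attenuation range.

    Total counts equal the number of input values.  A degenerate range
    (all values identical) yields a single bin centred on that value.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot histogram zero voxels")
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < bin_width:
        mid = 0.5 * (lo + hi)
        edges = np.array([mid - bin_width / 2, mid + bin_width / 2])
    else:
        n = int(np.ceil((hi - lo) / bin_width))
        edges = lo + bin_width * np.arange(n + 1)
        edges[-1] = max(edges[-1], hi + 1e-12)  # keep the max value inside
    counts, edges = np.histogram(v, bins=edges)
    return SliceHistogram(edges, counts.astype(float), slice_index,
                          equivalent_radius_cm)


def dual_gaussian(x, a1, b1, c1, a2, b2, c2):
    """Sum of two Gaussians in the C-width convention (sigma = C/sqrt(2))."""
    x = np.asarray(x, dtype=float)
    return (a1 * np.exp(-((x - b1) / c1) ** 2)
            + a2 * np.exp(-((x - b2) / c2) ** 2))


@dataclass
class GaussianPairFit:
    """Fitted dual-Gaussian parameters, component-ordered so b1 < b2
    (component 1 = fat, component 2 = gland)."""

    a1: float
    b1: float
    c1: float
    a2: float
    b2: float
    c2: float
    r_squared: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.b2 < self.b1:  # enforce fat-first ordering
            (self.a1, self.b1, self.c1, self.a2, self.b2, self.c2) = (
                self.a2, self.b2, self.c2, self.a1, self.b1, self.c1)
        self.c1, self.c2 = abs(self.c1), abs(self.c2)

    @property
    def params(self) -> tuple[float, ...]:
        return (self.a1, self.b1, self.c1, self.a2, self.b2, self.c2)

    def __call__(self, x):
        return dual_gaussian(x, *self.params)

    def component(self, x, which: int):
        a, b, c = (self.a1, self.b1, self.c1) if which == 1 else \
                  (self.a2, self.b2, self.c2)
        return a * np.exp(-((np.asarray(x, dtype=float) - b) / c) ** 2)


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, ...]:
    """Seed the nonlinear fit from the two most prominent local maxima of a
    lightly smoothed histogram; widths from a FWHM estimate."""
    ys = ndimage.gaussian_filter1d(y, sigma=2.0)
    peaks, props = find_peaks(ys, prominence=0.02 * max(ys.max(), 1e-12))
    if len(peaks) >= 2:
        top = peaks[np.argsort(props["prominences"])[-2:]]
        i1, i2 = sorted(top)
        b1, b2 = x[i1], x[i2]
        a1, a2 = max(y[i1], 1e-9), max(y[i2], 1e-9)
    else:
        mean = np.average(x, weights=np.maximum(y, 0) + 1e-12)
        sd = np.sqrt(np.average((x - mean) ** 2,
                                weights=np.maximum(y, 0) + 1e-12))
        b1, b2 = mean - sd, mean + sd
        a1 = a2 = max(ys.max(), 1e-9)
    # FWHM of the taller peak -> C (fwhm = 2 sqrt(ln 2) C)
    half = 0.5 * ys.max()
    above = x[ys >= half]
    fwhm = (above[-1] - above[0]) if len(above) > 1 else \
        4 * (x[1] - x[0] if len(x) > 1 else 1e-3)
    c = max(fwhm / (2 * np.sqrt(np.log(2))) / 2, x[1] - x[0]
            if len(x) > 1 else 1e-3)
    return (a1, b1, c, a2, b2, c)


def fit_dual_gaussian(hist: SliceHistogram,
                      init: tuple[float, ...] | None = None
                      ) -> GaussianPairFit:
    """Nonlinear least-squares fit of the dual-Gaussian model to the
    (bin centre, count) pairs.  Non-convergence is reported via the
    ``converged`` flag, never raised."""
    x, y = hist.centers, hist.counts
    n_nz = int((y > 0).sum())
    if n_nz < 2:
        return GaussianPairFit(0, 0, 1e-6, 0, 1e-9, 1e-6, float("nan"),
                               converged=False)
    if n_nz < 6:
        # too few bins for a free 6-parameter fit, but two separated
        # populations (e.g. noiseless two-value data) are still resolvable:
        # place a narrow component on each of the two tallest bins
        nz = np.flatnonzero(y > 0)
        top = nz[np.argsort(y[nz])[-2:]]
        i1, i2 = sorted(top)
        if i1 == i2:
            return GaussianPairFit(0, 0, 1e-6, 0, 1e-9, 1e-6, float("nan"),
                                   converged=False)
        w = hist.bin_width / 2
        fit = GaussianPairFit(float(y[i1]), float(x[i1]), w,
                              float(y[i2]), float(x[i2]), w, converged=True)
        resid = y - fit(x)
        sst = float(((y - y.mean()) ** 2).sum())
        fit.r_squared = 1.0 - float((resid**2).sum()) / sst if sst > 0 \
            else float("nan")
        return fit
    p0 = init if init is not None else _initial_guess(x, y)
    span = x[-1] - x[0] if len(x) > 1 else 1.0
    lo = [0, x[0] - span, 1e-6 * span, 0, x[0] - span, 1e-6 * span]
    hi = [np.inf, x[-1] + span, 10 * span, np.inf, x[-1] + span, 10 * span]
    p0 = np.clip(p0, lo, hi)
    try:
        popt, _ = optimize.curve_fit(dual_gaussian, x, y, p0=p0,
                                     bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError):
        return GaussianPairFit(*p0, float("nan"), converged=False)
    fit = GaussianPairFit(*popt, converged=True)
    if fit.b2 - fit.b1 < 0.2 * max(fit.c1, fit.c2):
        # co-located components: the dual model is non-identifiable on
        # effectively single-Gaussian data; refit one component and report
        # a vanishing second amplitude so downstream thresholds flag it
        def single(xx, a, b, c):
            return a * np.exp(-((xx - b) / c) ** 2)
        try:
            ps, _ = optimize.curve_fit(
                single, x, y, p0=(fit.a1 + fit.a2,
                                  0.5 * (fit.b1 + fit.b2),
                                  max(fit.c1, fit.c2)), maxfev=10000)
            fit = GaussianPairFit(ps[0], ps[1], abs(ps[2]), 0.0,
                                  ps[1] + abs(ps[2]), abs(ps[2]),
                                  converged=True)
        except (RuntimeError, ValueError):
            pass
    resid = y - fit(x)
    sst = float(((y - y.mean()) ** 2).sum())
    fit.r_squared = 1.0 - float((resid**2).sum()) / sst if sst > 0 \
        else float("nan")
    return fit


def _check_fit(fit: GaussianPairFit, min_amp_ratio: float = 0.01) -> None:
    if not fit.converged:
        raise ThresholdError("fit did not converge")
    amax = max(fit.a1, fit.a2)
    if amax <= 0 or min(fit.a1, fit.a2) < min_amp_ratio * amax:
        raise ThresholdError("one component amplitude is negligible; "
                             "slice is effectively single-tissue")


def threshold_minimum(fit: GaussianPairFit,
                      resolution: float = DEFAULT_BIN_WIDTH / 100
                      ) -> float:
    """Interior minimum of the fitted sum between the two centroids.

    Grid search at ``resolution`` followed by bounded polish; raises
    :class:`ThresholdError` when the mixture is monotone between the
    centroids (no interior minimum)."""
    _check_fit(fit)
    b1, b2 = fit.b1, fit.b2
    if b2 - b1 <= resolution:
        raise ThresholdError("centroids coincide; no interior minimum")
    n = max(int(np.ceil((b2 - b1) / resolution)) + 1, 101)
    xs = np.linspace(b1, b2, n)
    ys = fit(xs)
    k = int(np.argmin(ys))
    if k in (0, n - 1):
        raise ThresholdError("no interior minimum between centroids")
    res = optimize.minimize_scalar(fit, bounds=(xs[k - 1], xs[k + 1]),
                                   method="bounded",
                                   options={"xatol": resolution / 10})
    return float(res.x)


def threshold_crosspoint(fit: GaussianPairFit) -> float:
    """Attenuation where the two fitted components are equal, between the
    centroids.  Closed form: taking logs of
    A1 exp(-(x-B1)^2/C1^2) = A2 exp(-(x-B2)^2/C2^2) gives a quadratic in x;
    the root in (B1, B2) is unique because the component log-ratio is
    strictly decreasing there.  May lie on either side of the mixture
    minimum."""
    _check_fit(fit)
    a1, b1, c1, a2, b2, c2 = fit.params
    lr = np.log(a1 / a2)
    # (x-b1)^2/c1^2 - (x-b2)^2/c2^2 = log(a1/a2)
    qa = 1.0 / c1**2 - 1.0 / c2**2
    qb = -2.0 * b1 / c1**2 + 2.0 * b2 / c2**2
    qc = b1**2 / c1**2 - b2**2 / c2**2 - lr
    eps = 1e-9 * (b2 - b1 if b2 > b1 else 1.0)
    if abs(qa) < 1e-12 / max(c1, c2) ** 2:  # equal widths -> linear
        if abs(qb) < 1e-300:
            raise ThresholdError("components identical; no crossing")
        roots = [-qc / qb]
    else:
        disc = qb**2 - 4 * qa * qc
        if disc < 0:
            raise ThresholdError("no real crossing between components")
        sq = np.sqrt(disc)
        roots = [(-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)]
    inside = [r for r in roots if b1 - eps <= r <= b2 + eps]
    if not inside:
        raise ThresholdError("no crossing between the centroids")
    return float(min(inside, key=lambda r: abs(r - 0.5 * (b1 + b2))))


def _component_cdf_mass(a: float, b: float, c: float, t) -> np.ndarray:
    """Area under A exp(-(x-B)^2/C^2) from -inf to t."""
    return a * c * np.sqrt(np.pi) / 2 * (1.0 + erf((np.asarray(t, dtype=float)
                                                    - b) / c))


@dataclass
class PurityThresholds:
    """Per-slice purity threshold pair.

    Voxels at or below ``t_fat`` form a region that is at least
    ``purity_fat`` fat by fitted-component mass; voxels at or above
    ``t_gland`` are at least ``purity_gland`` gland.  ``attained`` is False
    where the 95% target was unreachable and the maximising threshold was
    used instead."""

    t_fat: float
    t_gland: float
    purity_fat: float
    purity_gland: float
    attained_fat: bool = True
    attained_gland: bool = True


def threshold_purity(fit: GaussianPairFit, target: float = 0.95,
                     tol: float = DEFAULT_BIN_WIDTH / 100
                     ) -> PurityThresholds:
    """Iteratively find the widest thresholds whose selected regions are at
    least ``target`` pure by the fitted component integrals (error-function
    Gaussian masses).  Where the components overlap so much that the target
    purity is unreachable, the purity-maximising threshold is returned with
    the achieved purity, flagged via ``attained_*``."""
    _check_fit(fit)
    a1, b1, c1, a2, b2, c2 = fit.params

    def fat_purity(t):
        i1 = _component_cdf_mass(a1, b1, c1, t)
        i2 = _component_cdf_mass(a2, b2, c2, t)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(i1 + i2 > 0, i1 / (i1 + i2), 1.0)

    def gland_purity(t):
        j1 = _component_cdf_mass(a1, b1, c1, t)
        j2 = _component_cdf_mass(a2, b2, c2, t)
        tot1 = _component_cdf_mass(a1, b1, c1, np.inf)
        tot2 = _component_cdf_mass(a2, b2, c2, np.inf)
        r1, r2 = tot1 - j1, tot2 - j2
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(r1 + r2 > 0, r2 / (r1 + r2), 1.0)

    lo = b1 - 4 * max(c1, c2)
    hi = b2 + 4 * max(c1, c2)
    grid = np.linspace(lo, hi, 2001)

    def solve(purity_fn, want_largest: bool):
        p = purity_fn(grid)
        ok = np.flatnonzero(p >= target)
        if ok.size == 0:
            k = int(np.argmax(p))
            return float(grid[k]), float(p[k]), False
        k = int(ok[-1]) if want_largest else int(ok[0])
        # bisect into the adjacent failing cell for sub-grid precision
        if want_largest and k + 1 < len(grid):
            a_, b_ = grid[k], grid[k + 1]
            while b_ - a_ > tol:
                m = 0.5 * (a_ + b_)
                if purity_fn(m) >= target:
                    a_ = m
                else:
                    b_ = m
            t = a_
        elif not want_largest and k - 1 >= 0:
            a_, b_ = grid[k - 1], grid[k]
            while b_ - a_ > tol:
                m = 0.5 * (a_ + b_)
                if purity_fn(m) >= target:
                    b_ = m
                else:
                    a_ = m
            t = b_
        else:
            t = grid[k]
        return float(t), float(purity_fn(t)), True

    t_fat, p_fat, ok_fat = solve(fat_purity, want_largest=True)
    t_gland, p_gland, ok_gland = solve(gland_purity, want_largest=False)
    return PurityThresholds(t_fat, t_gland, p_fat, p_gland, ok_fat, ok_gland)


@dataclass
class TissueMasks:
    """Fat/gland segmentation of a breast volume.

    ``thresholds`` tabulates, per slice (or one "global" row), the applied
    threshold(s), achieved purity where relevant, fit quality, and whether
    the slice fell back to the global threshold.
    """

    fat_mask: np.ndarray
    gland_mask: np.ndarray
    method: str
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    thresholds: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.fat_mask = np.asarray(self.fat_mask, dtype=bool)
        self.gland_mask = np.asarray(self.gland_mask, dtype=bool)
        if (self.fat_mask & self.gland_mask).any():
            raise ValueError("fat and gland masks must be disjoint")

    def gland_fraction(self) -> float:
        n_g = int(self.gland_mask.sum())
        n_f = int(self.fat_mask.sum())
        if n_g + n_f == 0:
            raise ValueError("empty segmentation")
        return n_g / (n_g + n_f)

    def thresholds_to_csv(self, path: str) -> None:
        if self.thresholds is not None:
            self.thresholds.to_csv(path, index=False)


def _global_fit(values: np.ndarray, bin_width: float) -> GaussianPairFit:
    hist = build_histogram(values, bin_width, slice_index="global")
    return fit_dual_gaussian(hist)


def _apply_binary(values, thr):
    fat = values <= thr  # ties assigned to fat (documented convention)
    return fat, ~fat


def _apply_purity(values, pt: PurityThresholds):
    if pt.t_fat >= pt.t_gland:
        # well-separated components: pure bands overlap, split at midpoint
        mid = 0.5 * (pt.t_fat + pt.t_gland)
        return values <= mid, values > mid
    return values <= pt.t_fat, values >= pt.t_gland


def segment_volume(ct: VoxelGrid, mask: BreastMask, method: str = "minimum",
                   scope: str = "global",
                   bin_width: float = DEFAULT_BIN_WIDTH,
                   min_slice_voxels: int = MIN_SLICE_VOXELS,
                   purity_target: float = 0.95) -> TissueMasks:
    """Segment the in-mask breast volume into fat and gland.

    ``scope='global'`` fits the whole-breast histogram once (permitted only
    with ``method='minimum'``); ``scope='per_slice'`` fits each axial slice
    independently (``crosspoint`` and ``purity95``).  Slices with too few
    voxels or failed fits fall back to the global threshold and are flagged
    in the thresholds table.
    """
    if method not in ("minimum", "crosspoint", "purity95"):
        raise ValueError(f"unknown method {method!r}")
    if scope not in ("global", "per_slice"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "global" and method != "minimum":
        raise ValueError("global scope is defined for the minimum method; "
                         "use per_slice for crosspoint/purity95")
    m = mask.mask
    if m.shape != ct.shape:
        raise ValueError("mask and CT must share a grid")
    vals = ct.values[m]
    if vals.size == 0:
        raise ValueError("breast mask is empty")

    gfit = _global_fit(vals, bin_width)
    try:
        g_thr = threshold_minimum(gfit, resolution=bin_width / 100)
    except ThresholdError:
        if not gfit.converged:
            g_thr = float(np.median(vals))
        else:
            g_thr = 0.5 * (gfit.b1 + gfit.b2)

    fat = np.zeros(ct.shape, dtype=bool)
    gland = np.zeros(ct.shape, dtype=bool)
    rows = []

    if scope == "global":
        f, g = _apply_binary(ct.values, g_thr)
        fat, gland = f & m, g & m
        rows.append({"slice_index": "global", "threshold": g_thr,
                     "t_fat": np.nan, "t_gland": np.nan,
                     "purity_achieved": np.nan,
                     "r_squared": gfit.r_squared, "fallback": False})
        tbl = pd.DataFrame(rows)
        return TissueMasks(fat, gland, method, ct.spacing, ct.origin, tbl)

    any_ok = False
    for z in range(ct.shape[0]):
        sm = m[z]
        if not sm.any():
            continue
        sv = ct.values[z][sm]
        row = {"slice_index": z, "threshold": np.nan, "t_fat": np.nan,
               "t_gland": np.nan, "purity_achieved": np.nan,
               "r_squared": np.nan, "fallback": True}
        applied = None
        if sv.size >= min_slice_voxels:
            hist = build_histogram(sv, bin_width, slice_index=z)
            fit = fit_dual_gaussian(hist)
            row["r_squared"] = fit.r_squared
            try:
                if method == "minimum":
                    thr = threshold_minimum(fit, resolution=bin_width / 100)
                    applied = ("binary", thr)
                    row.update(threshold=thr, fallback=False)
                elif method == "crosspoint":
                    thr = threshold_crosspoint(fit)
                    applied = ("binary", thr)
                    row.update(threshold=thr, fallback=False)
                else:
                    pt = threshold_purity(fit, target=purity_target,
                                          tol=bin_width / 100)
                    applied = ("purity", pt)
                    row.update(t_fat=pt.t_fat, t_gland=pt.t_gland,
                               purity_achieved=min(pt.purity_fat,
                                                   pt.purity_gland),
                               fallback=False)
            except ThresholdError as exc:
                logger.info("slice %d: %s; falling back to global "
                            "threshold", z, exc)
        if applied is None:
            applied = ("binary", g_thr)
            row["threshold"] = g_thr
        else:
            any_ok = True
        if applied[0] == "binary":
            f, g = _apply_binary(ct.values[z], applied[1])
        else:
            f, g = _apply_purity(ct.values[z], applied[1])
        fat[z], gland[z] = f & sm, g & sm
        rows.append(row)

    if not rows:
        raise ValueError("no slices contained breast voxels")
    if not any_ok and not gfit.converged:
        raise ValueError("all slices unfittable and global fit failed")
    tbl = pd.DataFrame(rows)
    return TissueMasks(fat, gland, method, ct.spacing, ct.origin, tbl)
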