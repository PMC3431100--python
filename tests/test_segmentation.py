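"""Dual-Gaussian histogram fitting and the three tissue thresholds.

The threshold operations are checked against independent oracles:
brute-force grid minimisation for the minimum threshold, the analytic
log-quadratic root (and bisection on the component difference) for the
cross-point, and numeric quadrature of the fitted components for the
purity criterion.
"""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.integrate import quad

import mibiquant as mq
from mibiquant.segmentation import (DEFAULT_BIN_WIDTH, ThresholdError,
                                    dual_gaussian)


def hist_from_params(params, lo, hi, bin_width=DEFAULT_BIN_WIDTH):
    """Noiseless histogram whose counts are the model evaluated at the bin
    centres."""
    edges = np.arange(lo, hi + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return mq.SliceHistogram(edges, dual_gaussian(centers, *params))


class TestBuildHistogram:
    def test_identical_values_single_bin(self):
        h = mq.build_histogram(np.full(1000, 0.2))
        assert (h.counts > 0).sum() == 1
        assert h.counts.sum() == 1000

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0.24, 0.03, 5000)
        h = mq.build_histogram(v)
        assert h.counts.sum() == 5000

    def test_two_delta_populations(self):
        v = np.concatenate([np.full(300, 0.20), np.full(200, 0.28)])
        h = mq.build_histogram(v, bin_width=0.002)
        nz = h.centers[h.counts > 0]
        assert len(nz) == 2
        assert np.allclose(sorted(nz), [0.20, 0.28], atol=0.002)
        assert h.counts.sum() == 500


class TestFitDualGaussian:
    PARAMS = (100.0, 0.20, 0.02, 60.0, 0.28, 0.02)

    def test_noiseless_parameter_recovery(self):
        h = hist_from_params(self.PARAMS, 0.14, 0.34)
        fit = mq.fit_dual_gaussian(h)
        assert fit.converged
        assert np.allclose(fit.params, self.PARAMS, rtol=0.01)
        assert fit.r_squared > 0.999

    def test_single_component_data_flags_downstream(self):
        params = (100.0, 0.22, 0.02, 0.0, 0.30, 0.02)
        h = hist_from_params(params, 0.14, 0.36)
        fit = mq.fit_dual_gaussian(h)
        amps = sorted([fit.a1, fit.a2])
        assert amps[0] < 0.01 * amps[1]
        with pytest.raises(ThresholdError):
            mq.threshold_minimum(fit)

    def test_component_order_invariance(self):
        h = hist_from_params(self.PARAMS, 0.14, 0.34)
        f1 = mq.fit_dual_gaussian(h, init=self.PARAMS)
        swapped = self.PARAMS[3:] + self.PARAMS[:3]
        f2 = mq.fit_dual_gaussian(h, init=swapped)
        assert np.allclose(f1.params, f2.params, rtol=1e-4)
        assert f1.b1 < f1.b2

    def test_underdetermined_histogram_flagged(self):
        h = mq.build_histogram(np.full(100, 0.2))
        assert not mq.fit_dual_gaussian(h).converged


class TestThresholdMinimum:
    def test_symmetric_midpoint(self):
        fit = mq.GaussianPairFit(50, 0.20, 0.02, 50, 0.28, 0.02)
        assert mq.threshold_minimum(fit) == pytest.approx(0.24, abs=1e-6)

    def test_brute_force_grid_oracle(self):
        fit = mq.GaussianPairFit(2, 0.0, 0.5, 1, 2.0, 0.5)
        xs = np.linspace(fit.b1, fit.b2, 200001)  # 1e-5 resolution
        oracle = xs[np.argmin(fit(xs))]
        assert mq.threshold_minimum(fit) == pytest.approx(oracle, abs=1e-5)

    def test_amplitude_scale_invariance(self):
        fit = mq.GaussianPairFit(2, 0.0, 0.5, 1, 2.0, 0.5)
        t0 = mq.threshold_minimum(fit)
        for c in (0.5, 3.0, 10.0):
            scaled = mq.GaussianPairFit(2 * c, 0.0, 0.5, c, 2.0, 0.5)
            assert mq.threshold_minimum(scaled) == pytest.approx(t0,
                                                                 abs=1e-6)

    def test_heavy_overlap_has_no_interior_minimum(self):
        fit = mq.GaussianPairFit(100, 0.20, 0.30, 1.5, 0.25, 0.30)
        with pytest.raises(ThresholdError):
            mq.threshold_minimum(fit)


class TestThresholdCrosspoint:
    def test_symmetric_case_coincides_with_minimum(self):
        fit = mq.GaussianPairFit(50, 0.20, 0.02, 50, 0.28, 0.02)
        assert mq.threshold_crosspoint(fit) == pytest.approx(0.24, abs=1e-9)
        assert mq.threshold_crosspoint(fit) == pytest.approx(
            mq.threshold_minimum(fit), abs=1e-5)

    def test_analytic_equal_width_case(self):
        # A1=2, A2=1, B=0/2, C=0.5: crossing at 1 + ln(2)/16
        fit = mq.GaussianPairFit(2, 0.0, 0.5, 1, 2.0, 0.5)
        expected = 1.0 + np.log(2) / 16.0
        assert mq.threshold_crosspoint(fit) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_bisection_oracle_unequal_widths(self):
        fit = mq.GaussianPairFit(80, 0.19, 0.015, 45, 0.29, 0.035)
        from scipy.optimize import brentq
        diff = lambda x: fit.component(x, 1) - fit.component(x, 2)
        oracle = brentq(diff, fit.b1, fit.b2, xtol=1e-12)
        assert mq.threshold_crosspoint(fit) == pytest.approx(oracle,
                                                             abs=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a1=st.floats(1.0, 100.0), a2=st.floats(1.0, 100.0),
           b1=st.floats(0.1, 0.22), gap=st.floats(0.04, 0.2),
           c=st.floats(0.005, 0.035))
    def test_equal_widths_cross_between_centroids(self, a1, a2, b1, gap, c):
        # existence condition for the equal-width crossing inside (B1, B2):
        # the log amplitude ratio must not exceed gap^2 / C^2
        assume(gap**2 > 1.2 * c**2 * abs(np.log(a1 / a2)))
        fit = mq.GaussianPairFit(a1, b1, c, a2, b1 + gap, c)
        t = mq.threshold_crosspoint(fit)
        assert fit.b1 <= t <= fit.b2
        assert fit.component(t, 1) == pytest.approx(fit.component(t, 2),
                                                    rel=1e-6)


def component_purity_by_quadrature(fit, t, tissue):
    """Independent oracle: purity of the region below (fat) or above
    (gland) t, by adaptive quadrature of the fitted components."""
    g1 = lambda x: fit.component(x, 1)
    g2 = lambda x: fit.component(x, 2)
    lo, hi = fit.b1 - 12 * fit.c1, fit.b2 + 12 * fit.c2
    if tissue == "fat":
        i1 = quad(g1, lo, t)[0]
        i2 = quad(g2, lo, t)[0]
        return i1 / (i1 + i2)
    i1 = quad(g1, t, hi)[0]
    i2 = quad(g2, t, hi)[0]
    return i2 / (i1 + i2)


class TestThresholdPurity:
    def test_separated_components_meet_target(self):
        fit = mq.GaussianPairFit(80, 0.20, 0.02, 50, 0.28, 0.02)
        pt = mq.threshold_purity(fit, target=0.95)
        assert pt.attained_fat and pt.attained_gland
        assert component_purity_by_quadrature(fit, pt.t_fat, "fat") \
            >= 0.95 - 1e-6
        assert component_purity_by_quadrature(fit, pt.t_gland, "gland") \
            >= 0.95 - 1e-6

    def test_identical_components_cap_at_half(self):
        fit = mq.GaussianPairFit(50, 0.239999, 0.02, 50, 0.24, 0.02)
        pt = mq.threshold_purity(fit, target=0.95)
        assert not pt.attained_fat and not pt.attained_gland
        assert pt.purity_fat == pytest.approx(0.5, abs=1e-3)
        assert pt.purity_gland == pytest.approx(0.5, abs=1e-3)

    def test_half_target_symmetric_midpoint(self):
        fit = mq.GaussianPairFit(50, 0.20, 0.02, 50, 0.28, 0.02)
        pt = mq.threshold_purity(fit, target=0.5)
        # symmetric mixture: 50% purity holds right up to the far side of
        # the other component; the thresholds bracket the midpoint
        assert pt.t_fat >= 0.24 - 1e-6
        assert pt.t_gland <= 0.24 + 1e-6

    def test_widely_separated_purities_near_one(self):
        fit = mq.GaussianPairFit(80, 0.10, 0.02, 50, 0.30, 0.02)
        pt = mq.threshold_purity(fit, target=0.95)
        mid = 0.20
        assert component_purity_by_quadrature(fit, mid, "fat") > 0.999
        assert component_purity_by_quadrature(fit, mid, "gland") > 0.999
        assert pt.purity_fat >= 0.95 and pt.purity_gland >= 0.95


@settings(deadline=None, max_examples=60, derandomize=True)
@given(a1=st.floats(10.0, 100.0), ratio=st.floats(0.1, 10.0),
       b1=st.floats(0.15, 0.22), sep_mult=st.floats(1.7, 6.0),
       c1=st.floats(0.008, 0.03), c2=st.floats(0.008, 0.03))
def test_thresholds_lie_between_centroids(a1, ratio, b1, sep_mult, c1, c2):
    """The minimum and cross-point thresholds fall inside (B1, B2) for
    amplitude ratios in [0.1, 10] once the separation comfortably exceeds
    the larger width (separation^2 > C^2 |ln ratio|, the analytic
    existence condition for the crossing)."""
    sep = sep_mult * max(c1, c2)
    assume(sep**2 > 1.2 * max(c1, c2) ** 2 * abs(np.log(ratio)))
    fit = mq.GaussianPairFit(a1, b1, c1, a1 * ratio, b1 + sep, c2)
    try:
        tmin = mq.threshold_minimum(fit)
        assert fit.b1 < tmin < fit.b2
    except ThresholdError:
        pass  # unimodal mixture near the bimodality boundary: flagged
    tcross = mq.threshold_crosspoint(fit)
    assert fit.b1 <= tcross <= fit.b2


class TestSegmentVolume:
    def test_noiseless_phantom_all_methods_exact(self, noiseless_labels,
                                                 noiseless_spec):
        ct = mq.ct_from_labels(noiseless_labels, noiseless_spec)
        mask = mq.strip_skin(ct, skin_peel_mm=2.0)
        truth = (noiseless_labels.grid == 2) & mask.mask
        for method, scope in [("minimum", "global"),
                              ("crosspoint", "per_slice"),
                              ("purity95", "per_slice")]:
            tm = mq.segment_volume(ct, mask, method=method, scope=scope,
                                   min_slice_voxels=200)
            assert np.array_equal(tm.gland_mask, truth), method

    def test_masks_disjoint_every_method(self, breast_ct, breast_mask):
        for method, scope in [("minimum", "global"),
                              ("crosspoint", "per_slice"),
                              ("purity95", "per_slice")]:
            tm = mq.segment_volume(breast_ct, breast_mask, method=method,
                                   scope=scope, min_slice_voxels=300)
            assert not (tm.fat_mask & tm.gland_mask).any()
            assert (tm.fat_mask | tm.gland_mask).sum() <= breast_mask.n_voxels

    def test_partition_for_binary_methods(self, breast_ct, breast_mask):
        tm = mq.segment_volume(breast_ct, breast_mask, "minimum", "global")
        assert ((tm.fat_mask | tm.gland_mask) == breast_mask.mask).all()

    def test_noisy_fraction_recovery(self, breast_labels, breast_spec,
                                     breast_ct, breast_mask):
        # default noise gives a two-class Bayes error well under 2%; every
        # method must land within 4 points of the programmed fraction
        truth = ((breast_labels.grid == 2) & breast_mask.mask).sum() / \
            breast_mask.n_voxels
        for method, scope in [("minimum", "global"),
                              ("crosspoint", "per_slice"),
                              ("purity95", "per_slice")]:
            tm = mq.segment_volume(breast_ct, breast_mask, method=method,
                                   scope=scope, min_slice_voxels=300)
            assert abs(tm.gland_fraction() - truth) < 0.04, method

    def test_per_slice_beats_global_under_radial_shift(self):
        spec = mq.PhantomSpec(voxel_mm=1.0, radius_cm=4.0, length_cm=6.0,
                              glandular_fraction=0.35,
                              radial_shift_slope=0.02, noise_sd=0.01,
                              seed=13)
        lab = mq.make_phantom(spec)
        ct = mq.ct_from_labels(lab, spec)
        mask = mq.strip_skin(ct, 2.0)
        truth = ((lab.grid == 2) & mask.mask).sum() / mask.n_voxels
        err = {}
        for method, scope in [("minimum", "global"),
                              ("crosspoint", "per_slice")]:
            tm = mq.segment_volume(ct, mask, method=method, scope=scope,
                                   min_slice_voxels=300)
            err[method] = abs(tm.gland_fraction() - truth)
        assert err["crosspoint"] <= err["minimum"]

    def test_global_scope_restricted_to_minimum(self, breast_ct,
                                                breast_mask):
        with pytest.raises(ValueError):
            mq.segment_volume(breast_ct, breast_mask, "crosspoint", "global")
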