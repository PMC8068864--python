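"""Synthetic-data generator: conservation, oracle agreement, determinism,
and ground-truth plumbing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condyn.coloc import manders, spearman
from condyn.frap import RoiSpec, extract_roi_trace, normalize_recovery
from condyn.simulate import (ColocSimConfig, FrapSimConfig, NoiseModel,
                             analytic_disk_recovery, simulate_coloc_pair,
                             simulate_frap_movie, simulate_phenotype_image)


def bessel_series_recovery(x, terms=60):
    """Independent oracle: e^-x (I0(x) + I1(x)) by direct series summation
    of the modified Bessel functions."""
    i0 = sum((x / 2.0) ** (2 * k) / math.factorial(k) ** 2
             for k in range(terms))
    i1 = sum((x / 2.0) ** (2 * k + 1)
             / (math.factorial(k) * math.factorial(k + 1))
             for k in range(terms))
    return np.exp(-x) * (i0 + i1)


class TestFrapMovie:
    def test_mass_conservation(self, small_diffusion_movie):
        """Reflective-boundary diffusion without noise or acquisition
        bleaching conserves total intensity after the bleach phase."""
        cfg, movie, _ = small_diffusion_movie
        totals = movie.frames.reshape(movie.n_frames, -1).sum(axis=1)
        post = totals[cfg.n_pre + cfg.n_bleach:]
        assert np.ptp(post) / post[0] < 1e-9

    def test_immobile_pool_does_not_recover(self):
        cfg = FrapSimConfig(grid_size=48, pixel_size=0.08, n_post=80,
                            diffusion_coeff=0.147, immobile_fraction=1.0,
                            bleach_roi=RoiSpec(kind="circle",
                                               center=(23.5, 23.5),
                                               radius=0.5), seed=0)
        movie, _ = simulate_frap_movie(cfg)
        trace = extract_roi_trace(movie, cfg.bleach_roi)
        post = trace[cfg.n_pre + cfg.n_bleach:]
        assert np.ptp(post) / post[0] < 1e-12
        curve = normalize_recovery(trace, cfg.n_pre, cfg.n_bleach,
                                   cfg.frame_interval)
        assert np.allclose(curve.values, 0.0, atol=1e-9)

    def test_matches_disk_oracle(self):
        """Pure-mobile disk bleach agrees with the closed-form recovery to
        <2% RMS when the ROI is small relative to the field."""
        d, r = 0.147, 0.5
        cfg = FrapSimConfig(grid_size=128, pixel_size=0.06, n_post=200,
                            n_bleach=1, bleach_depth=1.0, diffusion_coeff=d,
                            bleach_roi=RoiSpec(kind="circle",
                                               center=(63.5, 63.5), radius=r),
                            seed=0)
        movie, _ = simulate_frap_movie(cfg)
        trace = extract_roi_trace(movie, cfg.bleach_roi)
        rec = trace[cfg.n_pre + cfg.n_bleach:] / trace[:cfg.n_pre].mean()
        t = (np.arange(len(rec)) + 1) * cfg.frame_interval
        ana = analytic_disk_recovery(d, r, 1.0, t).values
        assert np.sqrt(np.mean((rec - ana) ** 2)) < 0.02

    def test_exchange_mode_recovery_is_exact_exponential(self):
        cfg = FrapSimConfig(grid_size=32, pixel_size=0.1, n_post=300,
                            immobile_fraction=0.4, kinetics="exchange",
                            exchange_rates=(np.log(2) / 1.6,), seed=0,
                            bleach_roi=RoiSpec(kind="circle",
                                               center=(15.5, 15.5),
                                               radius=0.6))
        movie, gt = simulate_frap_movie(cfg)
        curve = normalize_recovery(extract_roi_trace(movie, cfg.bleach_roi),
                                   cfg.n_pre, cfg.n_bleach,
                                   cfg.frame_interval)
        expected = 0.6 * (1 - np.exp(-curve.times * np.log(2) / 1.6))
        assert np.allclose(curve.values, expected, atol=1e-12)
        assert gt.mobile_fraction == pytest.approx(0.6)
        assert gt.half_times == pytest.approx((1.6,))

    def test_seed_determinism(self):
        cfg = dict(grid_size=48, pixel_size=0.08, n_post=30,
                   diffusion_coeff=0.1,
                   noise_model=NoiseModel.gaussian(0.05),
                   bleach_roi=RoiSpec(kind="circle", center=(23.5, 23.5),
                                      radius=0.5))
        m1, _ = simulate_frap_movie(FrapSimConfig(seed=42, **cfg))
        m2, _ = simulate_frap_movie(FrapSimConfig(seed=42, **cfg))
        m3, _ = simulate_frap_movie(FrapSimConfig(seed=43, **cfg))
        assert np.array_equal(m1.frames, m2.frames)
        assert not np.array_equal(m1.frames, m3.frames)

    def test_unstable_discretization_refused(self):
        cfg = FrapSimConfig(grid_size=32, pixel_size=0.005, n_post=10,
                            diffusion_coeff=50.0,
                            bleach_roi=RoiSpec(kind="circle",
                                               center=(15.5, 15.5),
                                               radius=0.02), seed=0)
        with pytest.raises(ValueError, match="sub-steps"):
            simulate_frap_movie(cfg)

    @pytest.mark.parametrize("bad", [
        dict(immobile_fraction=1.2), dict(bleach_depth=-0.1),
        dict(acq_bleach_rate=-1.0), dict(n_post=0),
        dict(kinetics="exchange"),  # missing exchange_rates
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            FrapSimConfig(**bad)


class TestAnalyticDiskRecovery:
    def test_hand_derived_points(self):
        """f(tau) and f(2*tau) match an independent Bessel-series
        evaluation (x = 2 tau / t, so t=tau -> x=2, t=2tau -> x=1)."""
        tau = 1.5 ** 2 / (4 * 0.147)
        curve = analytic_disk_recovery(0.147, 1.5, 1.0,
                                       np.array([tau, 2 * tau]))
        assert curve.values[0] == pytest.approx(bessel_series_recovery(2.0),
                                                abs=1e-9)
        assert curve.values[1] == pytest.approx(bessel_series_recovery(1.0),
                                                abs=1e-9)
        assert curve.values[0] == pytest.approx(0.5238, abs=1e-4)
        assert curve.values[1] == pytest.approx(0.6737, abs=1e-4)

    def test_limits(self):
        curve = analytic_disk_recovery(0.1, 1.0, 1.0,
                                       np.array([0.0, 1e7]))
        assert curve.values[0] == 0.0
        assert curve.values[1] == pytest.approx(1.0, abs=1e-3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(d=st.floats(0.01, 5.0), r=st.floats(0.1, 3.0),
           m=st.floats(0.0, 1.0))
    def test_monotone_and_bounded(self, d, r, m):
        t = np.linspace(0.0, 200.0, 400)
        v = analytic_disk_recovery(d, r, m, t).values
        assert np.all(np.diff(v) >= -1e-12)
        assert np.all(v <= m + 1e-12)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            analytic_disk_recovery(-0.1, 1.0, 1.0, np.array([1.0]))
        with pytest.raises(ValueError):
            analytic_disk_recovery(0.1, 1.0, 1.0, np.array([-1.0]))


class TestColocPair:
    def test_fully_shared_channels_identical(self):
        pair, gt = simulate_coloc_pair(ColocSimConfig(shared_fraction=1.0,
                                                      seed=3))
        assert np.array_equal(pair.channel_1, pair.channel_2)
        assert manders(pair)[0] == 1.0 and manders(pair)[1] == 1.0
        assert spearman(pair) == pytest.approx(1.0)

    def test_zero_spots_degenerate(self):
        pair, gt = simulate_coloc_pair(ColocSimConfig(
            n_spots_per_channel=0, seed=0))
        assert gt.degenerate
        assert np.ptp(pair.channel_1) == 0

    def test_overcrowded_mask_warns(self):
        with pytest.warns(UserWarning, match="spots"):
            simulate_coloc_pair(ColocSimConfig(image_size=16,
                                               n_spots_per_channel=500,
                                               seed=0))

    def test_determinism_and_ground_truth_counts(self):
        cfg = ColocSimConfig(shared_fraction=0.5, n_spots_per_channel=40,
                             seed=11)
        p1, g1 = simulate_coloc_pair(cfg)
        p2, g2 = simulate_coloc_pair(cfg)
        assert np.array_equal(p1.channel_1, p2.channel_1)
        assert len(g1.shared_centers) == 20
        assert len(g1.centers_1) == 40 and len(g1.centers_2) == 40


class TestPhenotypeImages:
    def test_condensed_ground_truth_geometry(self):
        img, gt = simulate_phenotype_image(
            "condensed", image_size=256, pixel_size=0.1, seed=1, n_disks=3,
            disk_diameter_range=(2.0, 2.0), texture_amplitude=0.0)
        assert gt.object_diameters_um == pytest.approx((2.0, 2.0, 2.0))
        from condyn.morphology import segment_condensates
        table = segment_condensates(img, 0.1, min_diameter=1.0,
                                    mask=gt.nucleus_mask)
        assert len(table) == 3
        assert np.allclose(table["equivalent_diameter_um"], 2.0, atol=0.1)

    def test_fibrous_width_ground_truth(self):
        img, gt = simulate_phenotype_image(
            "fibrous", image_size=128, pixel_size=0.013, seed=2, n_fibers=1,
            fiber_width_range=(200.0, 200.0))
        # FWHM in pixels: 200 nm / 13 nm/px
        assert gt.ridge_widths_nm[0] / 13.0 == pytest.approx(15.38, abs=0.01)

    def test_unresolvable_width_refused(self):
        with pytest.raises(ValueError, match="unresolvable"):
            simulate_phenotype_image("fibrous", pixel_size=0.13, seed=0,
                                     fiber_width_range=(150.0, 150.0))

    def test_diffuse_zero_texture_uniform(self):
        img, gt = simulate_phenotype_image("diffuse", seed=0,
                                           texture_amplitude=0.0)
        assert np.ptp(img[gt.nucleus_mask]) == 0

    def test_determinism(self):
        a, _ = simulate_phenotype_image("fibrous", seed=5)
        b, _ = simulate_phenotype_image("fibrous", seed=5)
        assert np.array_equal(a, b)
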