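"""Recovery-curve processing and exponential fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from condyn.frap import (SOUMPASIS_GAMMA, FrapFit, FrapMovie, RecoveryCurve,
                         RoiSpec, choose_model, correct_acquisition_bleach,
                         diffusion_coefficient, extract_roi_trace,
                         fit_biexponential, fit_single_exponential,
                         normalize_recovery, summarize_replicates)
from condyn.simulate import (FrapSimConfig, analytic_disk_recovery,
                             simulate_frap_movie)

from conftest import exp_recovery

TIMES = np.arange(1000) * 0.0232


def make_curve(values, times=TIMES):
    return RecoveryCurve(times=times, values=np.asarray(values, float))


class TestExtractRoiTrace:
    def _movie(self, frames):
        return FrapMovie(frames=np.asarray(frames, float), pixel_size=0.1,
                         frame_interval=0.1, n_pre=0, n_bleach=0)

    def test_constant_field(self):
        movie = self._movie(np.full((4, 16, 16), 5.0))
        roi = RoiSpec(kind="circle", center=(8, 8), radius=0.4)
        assert np.allclose(extract_roi_trace(movie, roi), 5.0)

    def test_mean_over_mixed_region(self):
        frame = np.zeros((10, 10))
        frame[:, 5:] = 10.0
        mask = np.zeros((10, 10), bool)
        mask[4, 4:6] = True  # one pixel of 0, one of 10
        movie = self._movie(frame[None])
        roi = RoiSpec(kind="freehand-mask", mask=mask)
        assert extract_roi_trace(movie, roi)[0] == pytest.approx(5.0)

    def test_single_pixel_roi(self):
        frames = np.arange(3 * 8 * 8, dtype=float).reshape(3, 8, 8)
        mask = np.zeros((8, 8), bool)
        mask[2, 3] = True
        movie = self._movie(frames)
        roi = RoiSpec(kind="freehand-mask", mask=mask)
        assert np.array_equal(extract_roi_trace(movie, roi),
                              frames[:, 2, 3])

    def test_roi_outside_frame_rejected(self):
        movie = self._movie(np.zeros((2, 16, 16)))
        roi = RoiSpec(kind="circle", center=(15, 8), radius=0.5)
        with pytest.raises(ValueError, match="outside"):
            extract_roi_trace(movie, roi)

    def test_empty_roi_rejected(self):
        movie = self._movie(np.zeros((2, 16, 16)))
        roi = RoiSpec(kind="freehand-mask", mask=np.zeros((16, 16), bool))
        with pytest.raises(ValueError, match="no pixels"):
            extract_roi_trace(movie, roi)

    def test_coast_band_is_annulus(self):
        movie = self._movie(np.zeros((1, 64, 64)))
        full = RoiSpec(kind="circle", center=(31.5, 31.5), radius=1.5)
        coast = RoiSpec(kind="circle", center=(31.5, 31.5), radius=1.5,
                        coast_width=0.3)
        from condyn.frap import roi_mask
        m_full = roi_mask(full, (64, 64), 0.1)
        m_coast = roi_mask(coast, (64, 64), 0.1)
        assert m_coast.sum() < m_full.sum()
        assert not (m_coast & ~m_full).any()


class TestAcquisitionBleachCorrection:
    def test_constant_reference_is_identity(self):
        target = np.linspace(1, 2, 50)
        ref = np.full(50, 3.0)
        assert np.allclose(correct_acquisition_bleach(target, ref, 10),
                           target)

    def test_shared_decay_cancels_up_to_pre_mean_factor(self):
        """A multiplicative decay common to target and reference cancels;
        the pre-bleach-mean convention leaves only a constant scale factor
        (the mean reference decay over the pre phase), which full-scale
        normalization removes downstream."""
        t = np.arange(100) * 0.1
        true = 1.0 + 0.5 * np.sin(t)
        decay = np.exp(-0.05 * t)
        corrected = correct_acquisition_bleach(true * decay, 2.7 * decay, 10)
        ratio = corrected / true
        assert np.ptp(ratio) < 1e-12
        assert ratio[0] == pytest.approx(decay[:10].mean())

    def test_corrects_simulated_acquisition_bleach(self):
        """Correcting a bleached-acquisition movie with a reference ROI
        reproduces the normalized recovery of the same-seed simulation
        without acquisition bleaching."""
        roi = RoiSpec(kind="circle", center=(23.5, 23.5), radius=0.6)
        ref_roi = RoiSpec(kind="circle", center=(8.0, 8.0), radius=0.4)
        common = dict(grid_size=48, pixel_size=0.1, n_post=200, seed=5,
                      kinetics="exchange", exchange_rates=(0.5,),
                      immobile_fraction=0.2, bleach_roi=roi)
        m_b, _ = simulate_frap_movie(FrapSimConfig(acq_bleach_rate=0.01,
                                                   **common))
        m_0, _ = simulate_frap_movie(FrapSimConfig(acq_bleach_rate=0.0,
                                                   **common))
        corrected = correct_acquisition_bleach(
            extract_roi_trace(m_b, roi), extract_roi_trace(m_b, ref_roi),
            m_b.n_pre)
        expected = extract_roi_trace(m_0, roi)
        # equal up to a constant scale, removed by normalization
        ratio = corrected / expected
        assert np.ptp(ratio) / ratio[0] < 1e-9
        got = normalize_recovery(corrected, 10, 10, 0.0232)
        want = normalize_recovery(expected, 10, 10, 0.0232)
        assert np.allclose(got.values, want.values, atol=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            correct_acquisition_bleach(np.ones(20), np.zeros(20), 5)

    def test_recovering_reference_warns(self):
        t = np.arange(200, dtype=float)
        ref = 1.0 + 0.002 * t
        with pytest.warns(UserWarning, match="recovery"):
            correct_acquisition_bleach(np.ones(200), ref, 10)


class TestNormalizeRecovery:
    def test_plateau_arithmetic(self):
        trace = np.array([100.0] * 10 + [70.0] * 10 + [40.0] + [80.0] * 20)
        curve = normalize_recovery(trace, 10, 10, 0.1)
        assert curve.values[0] == 0.0
        assert curve.values[-1] == pytest.approx((80 - 40) / (100 - 40))
        assert curve.pre_mean == pytest.approx(100.0)
        assert curve.times[0] == 0.0

    def test_no_bleach_detected(self):
        trace = np.full(40, 100.0)
        with pytest.raises(ValueError, match="no bleach"):
            normalize_recovery(trace, 10, 10, 0.1)

    def test_idempotent_on_normalized_curve(self):
        t = np.arange(200) * 0.1
        ana = analytic_disk_recovery(0.1, 0.5, 0.8, t).values
        trace = np.concatenate([np.ones(10), np.full(10, 0.3), ana])
        curve = normalize_recovery(trace, 10, 10, 0.1)
        assert np.allclose(curve.values, ana, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 6))
    def test_normalization_exactness(self, seed):
        """Pre-bleach mean maps to 1 and first post-bleach value to 0,
        exactly, for arbitrary noisy traces."""
        rng = np.random.default_rng(seed)
        trace = rng.uniform(10, 100, 60)
        curve = normalize_recovery(trace, 10, 10, 0.1)
        renorm = (trace - curve.post0) / (curve.pre_mean - curve.post0)
        assert renorm[:10].mean() == pytest.approx(1.0)
        assert curve.values[0] == 0.0


class TestSingleExponentialFit:
    @pytest.mark.parametrize("a, t_half", [(0.60, 3.6), (0.96, 0.5),
                                           (0.85, 1.6)])
    def test_noiseless_self_consistency(self, a, t_half):
        curve = make_curve(exp_recovery(TIMES, [a], [t_half]))
        fit = fit_single_exponential(curve)
        assert fit.fit_ok
        assert fit.mobile_fraction == pytest.approx(a, rel=1e-3)
        assert fit.half_times[0] == pytest.approx(t_half, rel=1e-3)

    def test_all_zero_curve_fails_gracefully(self):
        fit = fit_single_exponential(make_curve(np.zeros_like(TIMES)))
        assert not fit.fit_ok

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_single_exponential(make_curve(np.ones(5), TIMES[:5]))

    def test_fitted_curve_monotone_with_plateau_at_mobile_fraction(self):
        rng = np.random.default_rng(0)
        y = exp_recovery(TIMES, [0.7], [2.0]) + rng.normal(0, 0.02, len(TIMES))
        fit = fit_single_exponential(make_curve(y))
        a, k = fit.amplitudes[0], fit.rates[0]
        model = a * (1 - np.exp(-k * TIMES))
        assert np.all(np.diff(model) >= 0)
        assert model[-1] <= fit.mobile_fraction


class TestBiexponentialFit:
    def test_noiseless_fiber_regime(self):
        curve = make_curve(exp_recovery(TIMES, [0.25, 0.20], [0.2, 1.6]))
        fit = fit_biexponential(curve)
        assert fit.model == "biexp" and fit.fit_ok
        assert fit.half_times[0] == pytest.approx(0.2, rel=1e-2)
        assert fit.half_times[1] == pytest.approx(1.6, rel=1e-2)
        assert fit.mobile_fraction == pytest.approx(0.45, rel=1e-2)
        assert fit.rates[0] > fit.rates[1]

    def test_single_component_input_collapses(self):
        curve = make_curve(exp_recovery(TIMES, [0.6], [3.6]))
        with pytest.warns(UserWarning, match="unresolved"):
            fit = fit_biexponential(curve)
        assert fit.model == "single"
        assert "collapsed" in fit.notes

    def test_fixed_fast_rate(self):
        curve = make_curve(exp_recovery(TIMES, [0.25, 0.20], [0.2, 1.6]))
        kf = np.log(2) / 0.2
        fit = fit_biexponential(curve, fixed_fast_rate=kf)
        assert fit.rates[0] == pytest.approx(kf)
        assert fit.half_times[1] == pytest.approx(1.6, rel=1e-2)


class TestChooseModel:
    def test_prefers_single_on_single_data(self):
        curve = make_curve(exp_recovery(TIMES, [0.6], [3.6]))
        fit = choose_model(curve)
        assert fit.model == "single"
        assert set(fit.aicc_scores) == {"single", "biexp"}

    def test_prefers_biexp_on_separated_components(self):
        curve = make_curve(exp_recovery(TIMES, [0.25, 0.20], [0.2, 1.6]))
        fit = choose_model(curve)
        assert fit.model == "biexp"
        assert fit.aicc_scores["biexp"] < fit.aicc_scores["single"]


class TestDiffusionCoefficient:
    def test_full_frap_worked_example(self):
        # t1/2 = 3.6 s in a 3 um-diameter spot
        assert diffusion_coefficient(3.6, 1.5) == pytest.approx(0.140,
                                                                abs=0.001)

    def test_gamma_definition(self):
        assert diffusion_coefficient(1.0, 1.0) == pytest.approx(0.224,
                                                                abs=5e-4)
        # gamma is the half-recovery root of the disk curve mapped through
        # tau = r^2 / (4 D)
        from scipy.special import i0e, i1e
        x = 1.0 / (2.0 * SOUMPASIS_GAMMA)
        assert i0e(x) + i1e(x) == pytest.approx(0.5, abs=1e-12)

    def test_round_trip_through_closed_form(self):
        """The closed-form curve built with the returned D reaches half of
        its plateau at the input half-time."""
        t_half, r = 2.3, 1.1
        d = diffusion_coefficient(t_half, r)

        def f(t):
            return analytic_disk_recovery(d, r, 1.0,
                                          np.array([t])).values[0] - 0.5

        t_cross = brentq(f, 1e-6, 1e4)
        assert t_cross == pytest.approx(t_half, rel=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            diffusion_coefficient(0.0, 1.0)


class TestSummarizeReplicates:
    @staticmethod
    def _fit(t_half, mobile, ok=True):
        return FrapFit(model="single", amplitudes=(mobile,),
                       rates=(np.log(2) / t_half,), half_times=(t_half,),
                       mobile_fraction=mobile, residual_sse=0.0,
                       n_points=100, fit_ok=ok)

    def test_mean_and_sd(self):
        s = summarize_replicates([self._fit(3, 0.5), self._fit(4, 0.6),
                                  self._fit(5, 0.7)])
        assert s.mean_half_times[0] == pytest.approx(4.0)
        assert s.sd_half_times[0] == pytest.approx(1.0)
        assert s.mean_mobile == pytest.approx(0.6)

    def test_single_replicate_has_no_sd(self):
        s = summarize_replicates([self._fit(3, 0.5)])
        assert s.sd_half_times is None and s.sd_mobile is None

    def test_failed_fits_excluded_and_counted(self):
        s = summarize_replicates([self._fit(3, 0.5),
                                  self._fit(9, 9.9, ok=False)])
        assert s.n_fits == 1 and s.n_failed == 1

    def test_all_failed_is_error(self):
        with pytest.raises(ValueError, match="all fits failed"):
            summarize_replicates([self._fit(3, 0.5, ok=False)])
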