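"""Log-Gaussian pRF model: tuning function, BOLD prediction, fitting, HRF refit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numtopo import prf, synth
from numtopo import timeline as tl
from numtopo.hrf import HrfParams, two_gamma_hrf
from numtopo.prf import get_engine

C_HALF = np.sqrt(2 * np.log(2))


class TestTuningResponse:
    def test_peak_at_preferred_numerosity(self):
        assert prf.tuning_response(3.0, 3.0, 0.4) == pytest.approx(1.0)

    def test_one_sigma_point(self):
        assert prf.tuning_response(3.0 * np.exp(0.4), 3.0, 0.4) == pytest.approx(np.exp(-0.5))

    def test_half_maximum_at_fwhm_edges(self):
        pref, sig = 4.0, 0.6
        for sign in (+1, -1):
            n = np.exp(np.log(pref) + sign * sig * C_HALF)
            assert prf.tuning_response(n, pref, sig) == pytest.approx(0.5)

    def test_fwhm_identity(self):
        pref, sig = 2.5, 0.35
        expected = np.exp(np.log(pref) + C_HALF * sig) - np.exp(np.log(pref) - C_HALF * sig)
        assert prf.fwhm_linear(pref, sig) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            prf.tuning_response(-1.0, 3.0, 0.4)
        with pytest.raises(ValueError):
            prf.tuning_response(3.0, 3.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        pref=st.floats(0.5, 20.0),
        sig=st.floats(0.05, 2.0),
        delta=st.floats(0.01, 2.0),
    )
    def test_symmetric_in_log_numerosity(self, pref, sig, delta):
        hi = prf.tuning_response(np.exp(np.log(pref) + delta), pref, sig)
        lo = prf.tuning_response(np.exp(np.log(pref) - delta), pref, sig)
        assert hi == pytest.approx(lo, rel=1e-9)
        # strictly below the peak away from it
        assert hi < 1.0


class TestPredictBold:
    def test_all_absent_design_predicts_zero(self):
        run = tl.RunTimeline(events=(), tr=1.5, n_frames_total=20, n_frames_discarded=0, modality="haptic")
        pred = prf.predict_bold(run, 3.0, 0.4)
        np.testing.assert_allclose(pred, 0.0)

    def test_matches_bruteforce_convolution(self):
        """Single 3 s event: prediction equals an independently coded discrete convolution."""
        ev = tl.StimulusEvent(onset=3.0, duration=3.0, numerosity=4, condition="haptic_equal_size")
        run = tl.RunTimeline(events=(ev,), tr=1.5, n_frames_total=40, n_frames_discarded=0, modality="haptic")
        dt = 0.1
        pred = prf.predict_bold(run, 3.0, 0.5, dt=dt)

        # brute-force oracle: sample design, convolve, pick frame samples
        n = int(round(run.retained_duration / dt))
        trace = np.zeros(n)
        for i in range(n):
            t = i * dt
            if 3.0 <= t < 6.0:
                trace[i] = np.exp(-((np.log(4) - np.log(3.0)) ** 2) / (2 * 0.5**2))
        kernel = two_gamma_hrf(HrfParams(), dt) * dt
        full = np.convolve(trace, kernel)[:n]
        oracle = full[:: int(round(1.5 / dt))][: run.n_frames_retained]
        np.testing.assert_allclose(pred, oracle, atol=1e-12)

    def test_wide_tuning_approaches_onoff_prediction(self, haptic_run):
        engine = get_engine(haptic_run)
        wide = engine.predict(3.0, 50.0)
        onoff = engine.predict_onoff()
        r = np.corrcoef(wide, onoff)[0, 1]
        assert r > 0.9999

    def test_dt_coarser_than_event_rejected(self):
        ev = tl.StimulusEvent(onset=0.0, duration=0.3, numerosity=4, condition="visual")
        run = tl.RunTimeline(events=(ev,), tr=1.95, n_frames_total=10, n_frames_discarded=0, modality="visual")
        with pytest.raises(ValueError):
            prf.PredictionEngine(run, dt=0.65)


class TestFitPrf:
    def test_noiseless_recovery(self, haptic_run):
        truth = synth.VoxelTruth("tuned", pref=3.0, sigma_log=0.4, amplitude=2.0, baseline=50.0)
        y = synth.simulate_voxel(haptic_run, truth, noise_sd=0.0, seed=0)
        fit = prf.fit_prf(y, haptic_run)
        assert fit.pref == pytest.approx(3.0, rel=1e-3)
        assert fit.sigma_log == pytest.approx(0.4, rel=1e-3)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-3)
        assert fit.baseline == pytest.approx(50.0, rel=1e-3)
        assert fit.r2 > 1 - 1e-9

    def test_exact_grid_point_wins_without_refinement(self, haptic_run):
        grid = prf.DEFAULT_GRID
        pref, sig = grid.prefs[30], grid.sigmas[20]
        y = get_engine(haptic_run).predict(pref, sig)
        fit = prf.fit_prf(y, haptic_run, refine=False)
        assert fit.pref == pytest.approx(pref)
        assert fit.sigma_log == pytest.approx(sig)
        assert fit.r2 == pytest.approx(1.0)

    def test_r2_affine_invariant(self, haptic_run):
        truth = synth.VoxelTruth("tuned", pref=4.0, sigma_log=0.5)
        y = synth.simulate_voxel(haptic_run, truth, seed=11)
        f1 = prf.fit_prf(y, haptic_run)
        f2 = prf.fit_prf(5.0 * y + 300.0, haptic_run)
        assert f2.r2 == pytest.approx(f1.r2, rel=1e-9)
        assert f2.pref == pytest.approx(f1.pref, rel=1e-6)

    def test_estimates_allowed_outside_presented_range(self, haptic_run):
        truth = synth.VoxelTruth("tuned", pref=12.0, sigma_log=0.4)
        y = synth.simulate_voxel(haptic_run, truth, noise_sd=0.0, seed=0)
        fit = prf.fit_prf(y, haptic_run)
        assert fit.pref > 7.0

    def test_constant_series_degenerate(self, haptic_run):
        y = np.full(haptic_run.n_frames_retained, 5.0)
        fit = prf.fit_prf(y, haptic_run)
        assert fit.degenerate
        assert fit.r2 == 0.0

    def test_series_length_validated(self, haptic_run):
        with pytest.raises(ValueError):
            prf.fit_prf(np.zeros(10), haptic_run)


class TestRangeMask:
    def test_boundaries_closed(self):
        import pandas as pd

        fits = pd.DataFrame({"pref": [3.5, 0.8, 7.0, 1.0, 7.0001]})
        mask = prf.range_mask(fits, 1.0, 7.0)
        assert mask.tolist() == [True, False, True, True, False]

    def test_invalid_bounds(self):
        import pandas as pd

        with pytest.raises(ValueError):
            prf.range_mask(pd.DataFrame({"pref": [2.0]}), 7.0, 1.0)


class TestSubjectHrf:
    def test_peak_delay_recovery(self, haptic_run):
        true_hrf = HrfParams(peak_delay=7.0)
        truths = [
            synth.VoxelTruth("tuned", pref=p, sigma_log=s)
            for p, s in [(2, 0.3), (3, 0.4), (5, 0.5), (1.5, 0.25), (4, 0.45), (6, 0.6)]
        ]
        series = synth.simulate_voxels(haptic_run, truths, hrf=true_hrf, noise_sd=0.3, seed=3)
        fits0 = prf.fit_many(series, haptic_run)
        hrf_new, fits1 = prf.estimate_subject_hrf(series, fits0, haptic_run)
        assert abs(hrf_new.peak_delay - 7.0) < 0.5
        assert fits1["r2"].sum() >= fits0["r2"].sum() - 1e-9

    def test_already_canonical_is_stable(self, haptic_run):
        truths = [synth.VoxelTruth("tuned", pref=3.0, sigma_log=0.4)]
        series = synth.simulate_voxels(haptic_run, truths, noise_sd=0.0, seed=0)
        fits0 = prf.fit_many(series, haptic_run)
        hrf_new, fits1 = prf.estimate_subject_hrf(series, fits0, haptic_run)
        # a single noiseless voxel: refit keeps the perfect fit
        assert fits1["r2"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert abs(fits1["r2"].sum() - fits0["r2"].sum()) <= 1e-6

    def test_no_voxel_above_threshold_returns_canonical(self, haptic_run):
        rng = np.random.default_rng(0)
        series = rng.standard_normal((3, haptic_run.n_frames_retained))
        fits0 = prf.fit_many(series, haptic_run)
        fits0["r2"] = 0.01  # force all below threshold
        hrf0 = HrfParams()
        with pytest.warns(UserWarning):
            hrf_new, fits1 = prf.estimate_subject_hrf(series, fits0, haptic_run, hrf0)
        assert hrf_new == hrf0


def test_parameter_recovery_median_error(haptic_run):
    """Across simulated tuned voxels at R^2 ~ 0.5 noise, median relative
    preference error stays below 10%."""
    rng = np.random.default_rng(1234)
    prefs_true = np.exp(rng.uniform(np.log(1.5), np.log(6.0), size=30))
    sigmas_true = rng.uniform(0.25, 0.6, size=30)
    truths = [synth.VoxelTruth("tuned", pref=p, sigma_log=s) for p, s in zip(prefs_true, sigmas_true)]
    series = synth.simulate_voxels(haptic_run, truths, seed=99)
    fits = prf.fit_many(series, haptic_run)
    rel_err = np.abs(fits["pref"].to_numpy() - prefs_true) / prefs_true
    assert np.median(rel_err) < 0.10
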