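import numpy as np
import pytest

from loopscope.dynamics import (
    ExpFitResult,
    fit_exponential,
    pool_rate_tension,
    rate_vs_tension,
    smooth_trace,
)
from loopscope.segmentation import trace_from_truth


def exp_model(t, l0, lf, tau):
    return lf - (lf - l0) * np.exp(-t / tau)


class TestFitExponential:
    def test_exact_model_recovery(self):
        t = np.arange(200) * 0.2
        y = exp_model(t, 0.0, 20.0, 10.0)
        fit = fit_exponential(time_s=t, loop_kb=y, onset=0)
        assert fit.converged
        assert fit.loop_initial_kb == pytest.approx(0.0, abs=1e-6)
        assert fit.loop_final_kb == pytest.approx(20.0, rel=1e-6)
        assert fit.tau_s == pytest.approx(10.0, rel=1e-6)
        assert fit.initial_rate_kbps == pytest.approx(2.0, rel=1e-6)

    @pytest.mark.parametrize("l0,lf,tau", [(0.0, 20.0, 10.0), (3.0, 30.0, 4.0), (1.0, 12.0, 25.0)])
    def test_self_model_recovery_sub_1e6(self, l0, lf, tau):
        t = np.arange(300) * 0.1
        fit = fit_exponential(time_s=t, loop_kb=exp_model(t, l0, lf, tau), onset=0)
        assert fit.tau_s == pytest.approx(tau, rel=1e-6)
        assert fit.loop_final_kb == pytest.approx(lf, rel=1e-6)
        assert fit.initial_rate_kbps == pytest.approx((lf - l0) / tau, rel=1e-6)

    def test_constant_trace_flagged(self):
        t = np.arange(50) * 0.2
        fit = fit_exponential(time_s=t, loop_kb=np.full(50, 5.0))
        assert not fit.converged

    def test_rate_identity(self):
        t = np.arange(100) * 0.2
        fit = fit_exponential(time_s=t, loop_kb=exp_model(t, 2.0, 18.0, 7.0), onset=0)
        assert fit.initial_rate_kbps == pytest.approx(
            (fit.loop_final_kb - fit.loop_initial_kb) / fit.tau_s, rel=1e-12
        )

    def test_time_origin_shift_invariance(self):
        t = np.arange(150) * 0.2
        y = exp_model(t, 0.0, 20.0, 8.0)
        a = fit_exponential(time_s=t, loop_kb=y, onset=0)
        b = fit_exponential(time_s=t + 123.4, loop_kb=y, onset=0)
        assert a.initial_rate_kbps == pytest.approx(b.initial_rate_kbps, rel=1e-9)

    def test_simulated_event_rate_within_10pct(self, rng):
        from loopscope import ExtruderConfig, StrandConfig, simulate_extrusion

        # stall force coupled to RE0 keeps growth exponential-like
        strand = StrandConfig(end_to_end_um=0.47 * 18.0, contour_length_um=18.0,
                              n_frames=1000)
        ext = ExtruderConfig(mode="one_sided_left", rate_left_kbps=2.0,
                             stall_force_pN=0.47 - 0.175,
                             landing_position_kb=0.7 * 48.5)
        truth = simulate_extrusion(strand, ext)
        truth = truth.trimmed(int(truth.growth_end_frame() * 1.5))
        fit = fit_exponential(trace_from_truth(truth))
        assert fit.converged
        assert fit.initial_rate_kbps == pytest.approx(2.0, rel=0.10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(time_s=np.arange(10.0), loop_kb=np.arange(10.0))

    def test_convergence_gate_tolerance_recorded(self):
        t = np.arange(60) * 0.2
        fit = fit_exponential(time_s=t, loop_kb=exp_model(t, 0, 10, 5), onset=0)
        assert fit.rel_cost_tolerance == 1e-8


class TestSmooth:
    def test_quadratic_reproduced_exactly(self):
        t = np.arange(100, dtype=float)
        y = 3.0 + 0.5 * t - 0.01 * t**2
        np.testing.assert_allclose(smooth_trace(y), y, atol=1e-8)

    def test_white_noise_variance_reduced(self, rng):
        noise = rng.normal(0, 1.0, 500)
        out = smooth_trace(noise)
        assert out.std() < 0.5 * noise.std()

    def test_linear_ramp_mean_preserved(self):
        y = np.linspace(0, 10, 200)
        assert smooth_trace(y).mean() == pytest.approx(y.mean(), rel=1e-9)

    def test_short_trace_window_shrinks(self):
        y = np.arange(21, dtype=float) ** 2
        out = smooth_trace(y, window=63)
        np.testing.assert_allclose(out, y, atol=1e-8)  # still order-2 exact

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            smooth_trace(np.arange(4.0))

    def test_simulated_noisy_trace_fluctuation_reduced(self, one_sided_truth, rng):
        noisy = one_sided_truth.loop_kb + rng.normal(0, 1.0, one_sided_truth.n_frames)
        resid_raw = noisy - one_sided_truth.loop_kb
        resid_smooth = smooth_trace(noisy) - smooth_trace(one_sided_truth.loop_kb)
        assert resid_smooth.std() <= resid_raw.std() / 3


class TestRateVsTension:
    def test_endpoint_and_monotonicity(self, one_sided_truth, wlc_default):
        trace = trace_from_truth(one_sided_truth)
        fit = fit_exponential(trace)
        curve = rate_vs_tension(trace, fit, wlc_default)
        assert curve["rate_kbps"].iloc[0] == pytest.approx(
            fit.initial_rate_kbps, rel=1e-6
        )
        assert np.all(np.diff(curve["rate_kbps"]) <= 1e-12)
        # tension should rise as the loop grows
        assert curve["tension_pN"].iloc[-1] > curve["tension_pN"].iloc[0]

    def test_sg_rate_agrees_with_fit_rate_on_noisy_exponential(self, rng):
        # the two initial-rate estimators (exponential fit derivative and
        # Savitzky-Golay derivative) must agree on noisy realizations of
        # genuinely exponential growth
        import pandas as pd

        from loopscope.segmentation import LoopTrace
        from loopscope.wlc import WLCParams

        t = np.arange(300) * 0.2
        y = exp_model(t, 0.0, 18.0, 12.0) + rng.normal(0, 0.3, t.size)
        df = pd.DataFrame(
            {"frame": np.arange(300), "time_s": t, "loop_kb": y,
             "region_i_kb": (48.5 - y) / 2, "region_ii_kb": (48.5 - y) / 2,
             "loop_position_rel": 0.5, "boundary_contact": False, "flag": "ok"}
        )
        trace = LoopTrace(df, (10, 92), 0.1, 0.2)  # L = 8.2 um
        fit = fit_exponential(trace, onset=0)
        curve = rate_vs_tension(trace, fit, WLCParams(contour_length_um=18.0))
        sg0 = curve["rate_sg_kbps"].iloc[:5].mean()
        assert fit.initial_rate_kbps == pytest.approx(1.5, rel=0.1)
        assert sg0 == pytest.approx(fit.initial_rate_kbps, rel=0.15)

    def test_requires_converged_fit(self, one_sided_truth, wlc_default):
        trace = trace_from_truth(one_sided_truth)
        bad = ExpFitResult(0, 0, 1.0, 0.0, 0.0, converged=False)
        with pytest.raises(ValueError):
            rate_vs_tension(trace, bad, wlc_default)

    def test_pooled_curve_matches_linear_stall_law(self, wlc_default):
        from loopscope import ExtruderConfig, StrandConfig, simulate_extrusion

        curves = []
        r0, fs = 2.0, 0.3
        for re0 in (0.46, 0.48, 0.50):
            strand = StrandConfig(end_to_end_um=re0 * 18.0, contour_length_um=18.0,
                                  n_frames=900)
            ext = ExtruderConfig(mode="one_sided_left", rate_left_kbps=r0,
                                 stall_force_pN=fs, landing_position_kb=0.7 * 48.5)
            truth = simulate_extrusion(strand, ext)
            truth = truth.trimmed(int(truth.growth_end_frame() * 1.3))
            trace = trace_from_truth(truth)
            fit = fit_exponential(trace)
            curve = rate_vs_tension(trace, fit, wlc_default)
            # model-free per-frame rate: the Savitzky-Golay derivative
            curves.append(curve.assign(rate_kbps=curve["rate_sg_kbps"]))
        pooled = pool_rate_tension(curves, n_bins=6)
        # compare binned means against r0 * (1 - F/Fs)
        expected = r0 * np.clip(1 - pooled["tension_pN"] / fs, 0, None)
        mid = (pooled["tension_pN"] > 0.10) & (pooled["tension_pN"] < 0.27)
        np.testing.assert_allclose(
            pooled.loc[mid, "rate_mean_kbps"], expected[mid], rtol=0.15
        )


class TestPooling:
    def _fake_curve(self, offset=0.0):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": np.arange(20.0),
                "tension_pN": np.linspace(0.05, 0.3, 20),
                "rate_kbps": np.linspace(2.0, 0.1, 20) + offset,
                "rate_sg_kbps": np.linspace(2.0, 0.1, 20) + offset,
            }
        )

    def test_identical_curves_zero_sd(self):
        pooled = pool_rate_tension([self._fake_curve(), self._fake_curve()], n_bins=4)
        np.testing.assert_allclose(pooled["rate_sd_kbps"], 0.0, atol=1e-12)

    def test_offset_curves_mean_exact(self):
        pooled = pool_rate_tension(
            [self._fake_curve(0.0), self._fake_curve(1.0)], n_bins=4
        )
        base = pool_rate_tension([self._fake_curve(), self._fake_curve()], n_bins=4)
        np.testing.assert_allclose(
            pooled["rate_mean_kbps"], base["rate_mean_kbps"] + 0.5, rtol=1e-12
        )

    def test_needs_two_curves(self):
        with pytest.raises(ValueError):
            pool_rate_tension([self._fake_curve()])
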