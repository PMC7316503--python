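import numpy as np
import pytest

from loopscope import render_kymograph
from loopscope.segmentation import (
    LoopTrace,
    TraceRejected,
    fit_loop_gaussian,
    intensity_to_kb,
    locate_loop,
    partition_regions,
    trace_from_truth,
    track_trace,
)


def gaussian_profile(n, amp, mu, sigma, offset):
    x = np.arange(n, dtype=float)
    return amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2)) + offset


class TestLocate:
    def test_single_bump(self):
        prof = gaussian_profile(200, 100, 100, 3, 10)
        assert locate_loop(prof) == 100

    def test_flat_profile_no_loop(self):
        assert locate_loop(np.full(100, 42.0)) is None

    def test_anchor_span_respected(self):
        prof = gaussian_profile(200, 100, 150, 3, 10)
        prof[5] = 1000.0  # bright artifact outside anchors
        assert locate_loop(prof, anchors=(20, 180)) == 150

    def test_simulated_position_within_1px(self, one_sided_truth):
        kymo = render_kymograph(one_sided_truth, noiseless=True)
        k = 60
        al, ar = kymo.anchor_px
        found = locate_loop(kymo.data[k], (al, ar))
        true_px = al + one_sided_truth.loop_position_rel[k] * (ar - al)
        assert abs(found - true_px) <= 1.0

    def test_empty_span(self):
        with pytest.raises(ValueError):
            locate_loop(np.array([]))


class TestGaussianFit:
    def test_exact_recovery(self):
        prof = gaussian_profile(80, 500.0, 37.3, 2.1, 25.0)
        fit = fit_loop_gaussian(prof, 37, window_halfwidth_px=15)
        assert fit.converged
        assert fit.center_px == pytest.approx(37.3, abs=1e-6)
        assert fit.sigma_px == pytest.approx(2.1, abs=1e-6)
        assert fit.amplitude == pytest.approx(500.0, rel=1e-6)
        assert fit.offset == pytest.approx(25.0, rel=1e-6)

    def test_pure_offset_not_a_loop(self):
        fit = fit_loop_gaussian(np.full(60, 30.0), 30)
        assert not fit.converged
        assert fit.amplitude <= 1.0

    def test_noisy_simulated_frame(self, one_sided_truth):
        kymo = render_kymograph(one_sided_truth, rng=np.random.default_rng(9))
        k = 80
        al, ar = kymo.anchor_px
        from loopscope.kymo import subtract_background

        prof = subtract_background(kymo.data[k], 51)
        guess = locate_loop(prof, (al, ar))
        fit = fit_loop_gaussian(prof, guess)
        true_px = al + one_sided_truth.loop_position_rel[k] * (ar - al)
        assert fit.converged
        assert abs(fit.center_px - true_px) < 0.5
        assert fit.sigma_px == pytest.approx(
            one_sided_truth.strand.psf_sigma_px, rel=0.2
        )


class TestPartition:
    def test_stated_arithmetic_rule(self):
        # Gaussian with area-above-offset 400 in a ~20 px window, offset 10/px
        sigma = 20 / 4.0  # +/-2 sigma spans 20 px
        amp = 400.0 / (sigma * np.sqrt(2 * np.pi))
        prof = gaussian_profile(121, amp, 60.0, sigma, 10.0)
        fit = fit_loop_gaussian(prof, 60, window_halfwidth_px=45)
        part = partition_regions(prof, fit, (0, 120), total_kb=48.5)
        total = prof.sum() + (400.0 - (prof - 10.0)[50:71].sum())  # tails double-count
        lo, hi = part.loop_window
        n_win = hi - lo + 1
        sig_loop = 400.0
        sig_i = prof[:lo].sum() + 10.0 * n_win / 2
        sig_ii = prof[hi + 1 : 121].sum() + 10.0 * n_win / 2
        s = sig_loop + sig_i + sig_ii
        assert part.loop_kb == pytest.approx(48.5 * sig_loop / s, rel=1e-6)
        assert part.region_i_kb == pytest.approx(48.5 * sig_i / s, rel=1e-6)
        assert part.region_ii_kb == pytest.approx(48.5 * sig_ii / s, rel=1e-6)

    def test_zero_offset_no_passthrough(self):
        prof = gaussian_profile(101, 300.0, 50.0, 2.0, 0.0)
        fit = fit_loop_gaussian(prof, 50, window_halfwidth_px=20)
        part = partition_regions(prof, fit, (0, 100))
        # outer regions only hold the Gaussian tails beyond +/-2 sigma
        outer_frac = (part.region_i_kb + part.region_ii_kb) / 48.5
        assert outer_frac < 0.05

    def test_boundary_contact_flag(self):
        prof = gaussian_profile(60, 300.0, 5.0, 2.0, 10.0)
        fit = fit_loop_gaussian(prof, 5, window_halfwidth_px=12)
        part = partition_regions(prof, fit, (0, 59), boundary_margin_px=3)
        assert part.boundary_contact

    def test_noiseless_fraction_matches_truth(self, one_sided_truth):
        kymo = render_kymograph(one_sided_truth, noiseless=True)
        trace = track_trace(kymo)
        k = len(trace) - 5
        row = trace.frames.iloc[k]
        frame_idx = int(row["frame"])
        assert row["loop_kb"] / 48.5 == pytest.approx(
            one_sided_truth.loop_kb[frame_idx] / 48.5, abs=0.02
        )

    def test_requires_converged_fit(self):
        from loopscope.segmentation import LoopFit

        with pytest.raises(ValueError):
            partition_regions(
                np.zeros(50), LoopFit(25, 2, 0, 0, False), (0, 49)
            )


class TestKbConversion:
    def test_fraction_to_kb(self):
        loop, r1, r2 = intensity_to_kb(10.0, 45.0, 45.0)
        assert loop == pytest.approx(4.85)

    def test_conservation(self):
        loop, r1, r2 = intensity_to_kb(0.5, 0.25, 0.25)
        assert (loop, r1, r2) == pytest.approx((24.25, 12.125, 12.125))
        assert loop + r1 + r2 == pytest.approx(48.5, abs=1e-12)

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            intensity_to_kb(0.0, 0.0, 0.0)


class TestTrack:
    def test_static_loop_constant_trace(self, strand):
        from loopscope import ExtruderConfig, simulate_extrusion

        ext = ExtruderConfig(
            mode="one_sided_left", rate_left_kbps=1e-9, stall_force_pN=0.5,
            landing_position_kb=20.0, start_frame=0,
        )
        truth = simulate_extrusion(strand, ext)
        # paint a static 8 kb loop into the truth so there is a visible spot
        truth.extruded_left_kb[:] = 8.0
        truth.loop_kb[:] = 8.0
        kymo = render_kymograph(truth, noiseless=True)
        trace = track_trace(kymo)
        assert trace.frames["loop_kb"].std() < 0.01
        assert trace.frames["loop_position_rel"].std() < 1e-3

    def test_one_sided_drift_direction(self, one_sided_truth):
        # left-side reeling: region I shrinks, loop moves toward left anchor
        kymo = render_kymograph(one_sided_truth, noiseless=True)
        trace = track_trace(kymo)
        p = trace.frames["loop_position_rel"].to_numpy()
        assert p[-10:].mean() < p[:10].mean()
        truth_drift = (
            one_sided_truth.loop_position_rel[-10:].mean()
            - one_sided_truth.loop_position_rel[:10].mean()
        )
        assert truth_drift < 0

    def test_time_reversal_equivariance(self, noiseless_kymo):
        fwd = track_trace(noiseless_kymo, mode="global")
        rev_kymo = noiseless_kymo
        rev_kymo.data = rev_kymo.data[::-1].copy()
        rev = track_trace(rev_kymo, mode="global")
        a = fwd.frames["loop_kb"].to_numpy()
        b = rev.frames["loop_kb"].to_numpy()[::-1]
        n = min(a.size, b.size)
        np.testing.assert_allclose(a[:n], b[:n], atol=0.2)

    def test_rejects_mostly_flat_kymograph(self):
        rng = np.random.default_rng(0)
        data = rng.normal(100.0, 1.0, (40, 80))
        from loopscope.kymo import Kymograph

        kymo = Kymograph(data, 0.1, 0.2, (10, 70))
        with pytest.raises(TraceRejected):
            track_trace(kymo, median_kernel_px=None)

    def test_min_frames(self, noiseless_kymo):
        from loopscope.kymo import Kymograph

        short = Kymograph(
            noiseless_kymo.data[:10], 0.1, 0.2, noiseless_kymo.anchor_px
        )
        with pytest.raises(ValueError):
            track_trace(short)

    def test_intensity_scale_invariance(self, noiseless_kymo):
        t1 = track_trace(noiseless_kymo)
        noiseless_kymo.data = noiseless_kymo.data * 3.7
        t2 = track_trace(noiseless_kymo)
        np.testing.assert_allclose(
            t1.frames["loop_kb"], t2.frames["loop_kb"], rtol=1e-4
        )


class TestTraceObject:
    def test_conservation_all_frames(self, noiseless_kymo):
        trace = track_trace(noiseless_kymo)
        total = (
            trace.frames["loop_kb"]
            + trace.frames["region_i_kb"]
            + trace.frames["region_ii_kb"]
        )
        np.testing.assert_allclose(total, 48.5, rtol=1e-12)

    def test_csv_roundtrip(self, noiseless_kymo, tmp_path):
        trace = track_trace(noiseless_kymo)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = LoopTrace.from_csv(path)
        np.testing.assert_allclose(back.loop_kb, trace.loop_kb)
        assert back.anchor_px == trace.anchor_px
        assert back.pixel_size_um == trace.pixel_size_um

    def test_truth_trace_is_exact(self, one_sided_truth):
        trace = trace_from_truth(one_sided_truth)
        np.testing.assert_array_equal(trace.loop_kb, one_sided_truth.loop_kb)
        assert len(trace) == one_sided_truth.n_frames

    def test_monotone_time_enforced(self):
        import pandas as pd

        df = pd.DataFrame(
            {"time_s": [0.0, 0.2, 0.1], "loop_kb": [0, 1, 2]}
        )
        with pytest.raises(ValueError):
            LoopTrace(df, (0, 10), 0.1, 0.2)
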