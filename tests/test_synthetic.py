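"""Generator behaviour: determinism, geometry, forward-model consistency."""

import numpy as np
import pytest

from cortios import (
    AcquisitionConfig,
    ArtifactModel,
    FlowGroundTruth,
    HemodynamicTemplate,
    RoiSpec,
    ScheduleError,
    StimulusSchedule,
)
from cortios import synthetic as sd
from cortios import pipeline as pl


# ---------------------------------------------------------------------------
# vessel scenes
# ---------------------------------------------------------------------------

class TestVesselScene:
    def test_no_vessels_leaves_pure_parenchyma(self, small_config):
        scene = sd.make_vessel_scene(small_config, n_vessels=0, seed=1)
        assert not scene.vessel_mask.any()
        assert scene.parenchyma_mask.all()
        assert (scene.baseline_image > 0).all()

    def test_seeded_determinism_is_bit_identical(self, small_config):
        a = sd.make_vessel_scene(small_config, n_vessels=3, seed=7)
        b = sd.make_vessel_scene(small_config, n_vessels=3, seed=7)
        assert np.array_equal(a.baseline_image, b.baseline_image)
        assert np.array_equal(a.vessel_mask, b.vessel_mask)
        for pa, pb in zip(a.centerlines, b.centerlines):
            assert np.array_equal(pa, pb)

    def test_different_seeds_differ(self, small_config):
        a = sd.make_vessel_scene(small_config, n_vessels=3, seed=7)
        b = sd.make_vessel_scene(small_config, n_vessels=3, seed=8)
        assert not np.array_equal(a.vessel_mask, b.vessel_mask)

    def test_centerlines_lie_inside_vessel_mask(self, small_config):
        scene = sd.make_vessel_scene(small_config, n_vessels=3, seed=7)
        for path in scene.centerlines:
            rows = np.clip(np.rint(path[:, 0]).astype(int), 0, 63)
            cols = np.clip(np.rint(path[:, 1]).astype(int), 0, 63)
            assert scene.vessel_mask[rows, cols].all()

    def test_masks_are_disjoint_and_vessels_darker(self, scene):
        assert not (scene.vessel_mask & scene.parenchyma_mask).any()
        assert (scene.baseline_image[scene.vessel_mask].mean()
                < scene.baseline_image[scene.parenchyma_mask].mean())

    def test_negative_vessel_count_rejected(self, small_config):
        with pytest.raises(ValueError):
            sd.make_vessel_scene(small_config, n_vessels=-1)


# ---------------------------------------------------------------------------
# hemodynamic template
# ---------------------------------------------------------------------------

class TestHemodynamicTrace:
    def test_causal_zero_before_onset(self, green, red):
        t = np.linspace(-5.0, 0.0, 101, endpoint=False)
        assert (sd.hemodynamic_trace(green, t) == 0).all()
        assert (sd.hemodynamic_trace(red, t) == 0).all()

    @pytest.mark.parametrize("preset,trough,peak", [
        ("green", 2.5, 7.0),  # volume-weighted response
        ("red", 1.0, 3.5),    # oximetric response
    ])
    def test_extrema_at_template_times(self, preset, trough, peak):
        tpl = HemodynamicTemplate.preset(preset)
        t = np.linspace(0.0, 20.0, 20001)
        trace = sd.hemodynamic_trace(tpl, t)
        assert t[trace.argmin()] == pytest.approx(trough, abs=0.05)
        assert t[trace.argmax()] == pytest.approx(peak, abs=0.05)

    def test_dip_amplitude_at_dip_time(self, green):
        val = sd.hemodynamic_trace(green, np.array([green.dip_time_s]))[0]
        # overlap with the other lobes perturbs the extremum only slightly
        assert val == pytest.approx(green.dip_amp, rel=0.02)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            HemodynamicTemplate(dip_time_s=5.0, peak_time_s=2.0,
                                undershoot_time_s=13.0, dip_amp=-1e-3,
                                peak_amp=1e-3, undershoot_amp=-1e-3,
                                lobe_widths_s=(1.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# IOS stack rendering
# ---------------------------------------------------------------------------

class TestRenderIosStack:
    def test_all_zero_model_reproduces_baseline(self, scene, small_config,
                                                quiet_artifacts):
        schedule = StimulusSchedule(onset_frames=(150,), duration_s=1.5)
        stack, _ = sd.render_ios_stack(scene, None, quiet_artifacts, schedule,
                                       small_config, duration_s=10.0)
        assert np.array_equal(stack.data,
                              np.repeat(scene.baseline_image[:, :, None],
                                        stack.n_frames, axis=2))

    def test_noise_free_roi_trace_matches_template(self, scene, small_config,
                                                   green, quiet_artifacts):
        """Closed-form forward model: with zero artifacts and a single trial
        the pipeline's baseline-normalized ROI trace at the activation centre
        equals the template (ROI-weighted kernel factor) sample for sample."""
        schedule = StimulusSchedule(onset_frames=(120,), duration_s=1.5)
        center = sd.default_activation_center(scene)
        stack, _ = sd.render_ios_stack(scene, green, quiet_artifacts, schedule,
                                       small_config, duration_s=26.0,
                                       activation_center=center)
        raw = pl.segment_trials(stack, schedule, n_pre=90, n_post=570)
        tensor = pl.fractional_change(raw, n_pre=90, frame_rate_fps=30.0)
        avg = pl.normalize_to_baseline(pl.trial_average(tensor), n_pre=90,
                                       frame_rate_fps=30.0)
        r, c = center
        roi = RoiSpec.rectangle(r - 2, c - 2, 4, 4)
        trace = pl.roi_trace(avg, roi)
        t = (np.arange(trace.size) - 90) / 30.0
        expected = sd.hemodynamic_trace(green, t)
        # ROI-mean kernel weight: fit a single gain, then require pointwise match
        gain = float(trace @ expected / (expected @ expected))
        assert 0.8 < gain <= 1.0  # kernel peaks at 1 at the centre
        assert np.allclose(trace, gain * expected, atol=5e-6)

    def test_trigger_log_counts_onsets(self, scene, small_config, green,
                                       quiet_artifacts):
        schedule = StimulusSchedule(onset_frames=(100, 900, 1700, 2500, 3300))
        stack, log = sd.render_ios_stack(scene, green, quiet_artifacts,
                                         schedule, small_config)
        assert len(log) == 5
        assert list(log["onset_frame"]) == [100, 900, 1700, 2500, 3300]
        assert np.allclose(log["onset_time_s"], log["onset_frame"] / 30.0)

    def test_onset_outside_stack_is_schedule_error(self, scene, small_config,
                                                   green, quiet_artifacts):
        schedule = StimulusSchedule(onset_frames=(100, 10_000))
        with pytest.raises(ScheduleError):
            sd.render_ios_stack(scene, green, quiet_artifacts, schedule,
                                small_config, duration_s=20.0)

    def test_seeded_stack_determinism(self, small_config, green):
        sims = [sd.simulate_ios_session(small_config, green, n_trials=2,
                                        isi_range_s=(23.0, 27.0), start_s=4.0)
                for _ in range(2)]
        assert np.array_equal(sims[0].stack.data, sims[1].stack.data)
        assert sims[0].schedule.onset_frames == sims[1].schedule.onset_frames


# ---------------------------------------------------------------------------
# flow movies
# ---------------------------------------------------------------------------

def _xcorr_lag(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Sub-pixel lag of b relative to a via cross-correlation (oracle).

    The search is restricted to |lag| <= max_lag because a near-periodic
    band pattern is only identifiable modulo its period.
    """
    a = a - a.mean()
    b = b - b.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    # corr[k] = sum_i a[i] * b[i + k]: b = a shifted by +s peaks at k = s
    corr = np.array([np.dot(a[max(0, -k):len(a) - max(0, k)],
                            b[max(0, k):len(b) - max(0, -k)])
                     for k in lags])
    k = int(np.argmax(corr))
    refined = float(lags[k])
    if 0 < k < len(corr) - 1:  # parabolic refinement
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        refined += 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
    return refined


class TestRenderFlowMovie:
    def test_zero_speed_is_static(self, scene, small_config):
        truth = FlowGroundTruth(speed_mm_s=0.0)
        movie = sd.render_flow_movie(scene, truth, small_config,
                                     duration_s=0.5, noise_scale=0.0)
        assert np.array_equal(movie.data, movie.data[:, :, :1].repeat(
            movie.n_frames, axis=2))

    def test_parenchyma_is_static_under_flow(self, scene, small_config):
        truth = FlowGroundTruth(speed_mm_s=0.7)
        movie = sd.render_flow_movie(scene, truth, small_config,
                                     duration_s=0.5, noise_scale=0.0)
        outside = movie.data[~scene.vessel_mask]
        assert np.ptp(outside, axis=1).max() == 0.0

    def test_band_pattern_advances_at_ground_truth_speed(self, small_config):
        """Cross-correlation of line profiles n frames apart must show a lag
        of speed * n / (F * pitch) pixels, within half a pixel."""
        config = AcquisitionConfig(height_px=64, width_px=128,
                                   frame_rate_fps=30.0, pixel_pitch_um=7.5,
                                   seed=5)
        scene = sd.make_vessel_scene(config, n_vessels=1, seed=5)
        v = 0.25  # mm/s; 30 fps keeps the per-frame shift sub-band-width
        movie = sd.render_flow_movie(scene, FlowGroundTruth(speed_mm_s=v),
                                     config, duration_s=1.0, noise_scale=0.0)
        from cortios import kymograph as kg
        line = RoiSpec.line(scene.centerlines[0])
        ky = kg.sample_line(movie, line)
        # divide out the static baseline along the line so only the advected
        # modulation remains, then correlate within half a band period (4 px)
        baseline_profile = kg.sample_line(scene.baseline_image, line)
        mod = ky.matrix / baseline_profile[:, None]
        n = 3
        expected = v * 1e3 / (7.5 * 30.0) * n  # px of arclength
        lag = _xcorr_lag(mod[:, 0], mod[:, n], max_lag=4)
        assert lag == pytest.approx(expected, abs=0.5)
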