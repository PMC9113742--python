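"""Kymograph construction, ΔF/F0 normalisation, transient detection."""

import numpy as np
import pytest

from wormcal.kymograph import (
    Kymograph,
    average_peak,
    build_kymograph,
    caffeine_response,
    compute_dff,
    detect_transients,
)
from wormcal.pipeline import run_video_pipeline
from wormcal.synth import gen_worm_video

from conftest import small_params


def _grid_ts(dff, dt=0.1):
    f0 = np.full(dff.shape[0], 1.0)
    return detect_transients(np.asarray(dff, float), f0, dt)


class TestBuildKymograph:
    def test_uniform_worm_gives_constant_kymograph(self, default_config):
        params = small_params(noise_sd=0.0, transient_rate=0.0,
                              interior_fraction=1.0)  # uniform-intensity worm
        video, _ = gen_worm_video(params)
        res = run_video_pipeline(video, default_config)
        k = res["kymograph"].values
        assert np.ptp(k) / np.median(k) < 0.01

    def test_band_width_preserves_ordering_of_maxima(self, event_video, default_config):
        params, video, _ = event_video
        from wormcal.segment import extract_contour, register_contours, segment_frame

        contours = [extract_contour(segment_frame(f), i) for i, f in enumerate(video.frames)]
        seq = register_contours(contours)
        k1 = build_kymograph(video, seq, band_width=1)
        k3 = build_kymograph(video, seq, band_width=3)
        assert np.unravel_index(np.argmax(k1.values), k1.values.shape) == \
            np.unravel_index(np.argmax(k3.values), k3.values.shape)

    def test_scripted_event_at_kymograph_argmax(self, pipeline_on_event_video):
        params, gt, res = pipeline_on_event_video
        k = res["kymograph"]
        _, t_idx = np.unravel_index(np.argmax(k.values), k.values.shape)
        t_est = t_idx * k.frame_interval
        # the brightest sample must fall within 2 frames of a scripted event
        assert min(abs(t_est - t) for t in gt.event_times) <= 2 * k.frame_interval + 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            Kymograph(np.ones((1, 5)), 0.1)
        with pytest.raises(ValueError):
            Kymograph(np.full((5, 5), -1.0), 0.1)


class TestComputeDff:
    def test_constant_row_maps_to_zero(self):
        k = Kymograph(np.full((4, 50), 7.0), 0.1)
        dff, f0 = compute_dff(k)
        assert np.allclose(dff, 0.0)
        assert np.allclose(f0, 7.0)

    def test_known_amplitude_recovered_exactly(self):
        row = np.full(100, 10.0)
        row[40:45] = 20.0  # F0*(1+A) with A = 1
        k = Kymograph(np.tile(row, (3, 1)), 0.1)
        dff, _ = compute_dff(k)
        assert dff.max() == pytest.approx(1.0)
        assert dff.min() == pytest.approx(0.0)

    def test_detrend_removes_bleach(self):
        t = np.arange(200) * 0.1
        row = 100.0 * np.exp(-0.02 * t)
        k = Kymograph(np.tile(row, (3, 1)), 0.1)
        dff, _ = compute_dff(k, detrend=True)
        assert np.abs(dff).max() < 1e-6

    def test_nonpositive_f0_rejected(self):
        k = Kymograph(np.zeros((3, 50)), 0.1)
        with pytest.raises(ValueError):
            compute_dff(k)

    def test_amplitude_recovery_on_video(self, default_config):
        params = small_params(seed=12, transient_amplitude=0.8, transient_rate=0.5)
        video, gt = gen_worm_video(params)
        assert gt.event_times, "fixture seed must script at least one event"
        res = run_video_pipeline(video, default_config)
        assert res["dff"].max() == pytest.approx(0.8, rel=0.15)


class TestDetectTransients:
    def test_zero_grid_yields_no_events(self):
        assert len(_grid_ts(np.zeros((10, 100)))) == 0

    def test_two_disjoint_events_found_at_scripted_cells(self):
        dff = np.zeros((40, 100))
        dff[10, 20:28] = 1.0
        dff[30, 60:70] = 0.6
        ts = _grid_ts(dff)
        assert len(ts) == 2
        ev = sorted(ts.events, key=lambda e: e.time)
        assert ev[0].position == pytest.approx(10 / 40)
        assert 2.0 <= ev[0].time <= 2.8
        assert ev[1].peak_dff == pytest.approx(0.6)

    def test_single_sample_dropout_bridged(self):
        dff = np.zeros((10, 100))
        dff[5, 30:40] = 1.0
        dff[5, 34] = 0.0  # dropout
        ts = _grid_ts(dff)
        assert len(ts) == 1

    def test_short_blips_discarded(self):
        dff = np.zeros((10, 100))
        dff[5, 50] = 5.0  # one frame = 0.1 s < min_duration
        assert len(_grid_ts(dff)) == 0

    def test_nan_rejected(self):
        bad = np.zeros((5, 20))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            _grid_ts(bad)

    def test_nearby_fragments_merged_distant_events_kept(self):
        dff = np.zeros((100, 100))
        dff[50, 20:26] = 1.0
        dff[53, 27:33] = 0.9   # same event, jittered rows and a 1-frame gap
        dff[80, 60:70] = 0.7   # distinct event
        ts = _grid_ts(dff)
        assert len(ts) == 2


class TestSummaries:
    def test_average_peak_arithmetic(self):
        dff = np.zeros((10, 100))
        dff[2, 10:20] = 1.0
        dff[7, 60:70] = 0.5
        summary = average_peak(_grid_ts(dff))
        assert summary.mean_peak == pytest.approx(0.75)
        assert summary.n_events == 2

    def test_empty_set_flagged(self):
        summary = average_peak(_grid_ts(np.zeros((5, 50))))
        assert summary.mean_peak == 0.0
        assert summary.no_events

    def test_monotone_in_true_amplitude(self, default_config):
        estimates = []
        for amp in (0.4, 0.8):
            params = small_params(seed=19, transient_amplitude=amp,
                                  transient_rate=0.5, noise_sd=0.0)
            video, gt = gen_worm_video(params)
            res = run_video_pipeline(video, default_config)
            estimates.append(res["peak_summary"].mean_peak)
        assert estimates[0] < estimates[1]


class TestCaffeine:
    def test_no_event_no_responder(self):
        rng = np.random.default_rng(0)
        dff = rng.normal(0, 0.01, (50, 150))
        resp = caffeine_response(dff, 0.1, t_caffeine=5.0)
        assert not resp.responder

    def test_scripted_store_release_detected(self, default_config):
        params = small_params(duration=8.0, transient_rate=0.0,
                              caffeine_time=3.0, seed=2)
        video, _ = gen_worm_video(params)
        res = run_video_pipeline(video, default_config, t_caffeine=3.0)
        resp = res["caffeine"]
        assert resp.responder
        assert resp.latency < 1.0

    def test_high_flat_background_is_not_a_responder(self):
        # store-depleted phenotype: bright but flat — baseline high, no step
        dff = np.full((40, 120), 0.0)
        resp = caffeine_response(dff + 0.001, 0.1, t_caffeine=5.0)
        assert not resp.responder

    def test_window_truncated_with_warning(self):
        dff = np.zeros((10, 80))
        with pytest.warns(UserWarning, match="truncated"):
            caffeine_response(dff, 0.1, t_caffeine=7.0, window=10.0)
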