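"""Feature detection, Lucas-Kanade tracking, waveform and rate estimation."""

import numpy as np
import pytest

from vivorate import respirometry as rp
from vivorate import synthetic_video as sv
from vivorate.video import FrameSequence


def make_sine_signal(rate_bpm: float, fps: float = 30.0, duration_s: float = 20.0):
    t = np.arange(int(duration_s * fps)) / fps
    return rp.RespirationSignal(np.sin(2 * np.pi * rate_bpm / 60.0 * t), fps)


def make_track(point_id, series_2d, valid=None):
    series_2d = np.asarray(series_2d, float)
    if valid is None:
        valid = np.ones(len(series_2d), bool)
    pos = series_2d.copy()
    pos[~valid] = np.nan
    return rp.FeatureTrack(point_id=point_id, positions=pos, valid=valid)


class TestDetectFeatures:
    def test_speckle_roi_yields_full_ten_corners(self, clean_clip, clean_scenario):
        seq, _ = clean_clip
        roi = rp.RoiContour(sv.flank_roi(clean_scenario))
        seeds = rp.detect_features(seq, [roi])
        assert seeds.shape == (10, 2)

    def test_flat_roi_warns_and_contributes_nothing(self):
        from scipy.ndimage import gaussian_filter

        frames = np.full((3, 96, 96), 128, dtype=np.uint8)
        # 2-D speckle texture only in the right half; the left is flat.
        rng = np.random.default_rng(0)
        speckle = gaussian_filter(rng.uniform(size=(96, 48)), 1.2)
        speckle = (128 + 120 * (speckle - speckle.mean())).astype(np.uint8)
        frames[:, :, 48:] = speckle[None]
        seq = FrameSequence(frames, fps=30.0)
        flat = rp.RoiContour([[10, 10], [10, 40], [40, 40], [40, 10]])
        textured = rp.RoiContour([[10, 55], [10, 85], [40, 85], [40, 55]])
        with pytest.warns(UserWarning, match="no detectable corners"):
            seeds = rp.detect_features(seq, [flat, textured])
        assert len(seeds) >= 1

    def test_all_flat_rois_raise(self):
        frames = np.full((3, 64, 64), 100, dtype=np.uint8)
        seq = FrameSequence(frames, fps=30.0)
        roi = rp.RoiContour([[5, 5], [5, 50], [50, 50], [50, 5]])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no detectable corners"):
                rp.detect_features(seq, [roi])

    def test_seeds_lie_inside_their_polygons(self, clean_clip):
        from shapely.geometry import Point, Polygon

        seq, _ = clean_clip
        poly_a = np.array([[100, 90], [100, 130], [140, 130], [140, 90]], float)
        poly_b = np.array([[100, 135], [100, 170], [140, 170], [140, 135]], float)
        seeds = rp.detect_features(seq, [rp.RoiContour(poly_a), rp.RoiContour(poly_b)])
        assert len(seeds) <= 20
        union = [Polygon(poly_a), Polygon(poly_b)]
        assert all(any(p.contains(Point(s)) for p in union) for s in seeds)

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError, match="self-intersect"):
            rp.RoiContour([[0, 0], [10, 10], [0, 10], [10, 0]])


class TestTrackFeatures:
    def test_static_scene_keeps_points_fixed(self):
        sc = sv.BreathingScenario(amplitude_px=0.0, noise_sd=0.0, duration_s=4.0, seed=6)
        seq, _ = sv.render_breathing_clip(sc)
        seeds = rp.detect_features(seq, [rp.RoiContour(sv.flank_roi(sc))])
        tracks = rp.track_features(seq, seeds)
        for t in tracks:
            assert t.valid.all()
            drift = np.abs(t.positions - t.positions[0]).max()
            assert drift <= 0.05

    def test_displacement_recovered_within_fifth_of_pixel(self, clean_clip, clean_tracks):
        # Oracle: ground-truth offsets from the generator.
        _, truth = clean_clip
        d = truth.displacement_series - truth.displacement_series[0]
        for t in clean_tracks:
            err = (t.positions - t.positions[0]) - d
            rms = np.sqrt(np.nanmean(err**2))
            assert rms <= 0.2

    def test_patch_exit_invalidates_tracks_at_ground_truth_time(self):
        # Upward scene drift carries the flank out of the frame mid-clip.
        sc = sv.BreathingScenario(
            rate_bpm=150.0, duration_s=8.0, drift_px_per_s=(-20.0, 0.0), seed=13
        )
        seq, _ = sv.render_breathing_clip(sc)
        seeds = rp.detect_features(seq, [rp.RoiContour(sv.flank_roi(sc))])
        tracks = rp.track_features(seq, seeds)
        margin = 21 // 2 + 1
        for t in tracks:
            r0 = t.positions[0, 0]
            exit_frame = ((r0 - margin) / 20.0) * sc.fps  # when true row hits margin
            last_valid = int(np.nonzero(t.valid)[0].max())
            assert last_valid <= exit_frame + 3
            assert last_valid >= exit_frame - 0.15 * sc.fps
            assert not t.valid[last_valid + 1 :].any()  # no re-acquisition

    def test_all_points_lost_early_raises(self):
        rng = np.random.default_rng(1)
        frames = (rng.uniform(size=(30, 64, 64)) * 255).astype(np.uint8)  # pure noise
        seq = FrameSequence(frames, fps=30.0)
        with pytest.raises(RuntimeError, match="tracking lost"):
            rp.track_features(seq, np.array([[32.0, 32.0], [20.0, 40.0]]))


class TestBuildWaveform:
    def test_median_of_identical_sinusoids_is_that_sinusoid(self):
        fps = 30.0
        t = np.arange(300) / fps
        s = np.sin(2 * np.pi * 2.0 * t)
        tracks = [
            make_track(i, np.column_stack([100 + 2 * s, np.full_like(s, 50 + 5 * i)]))
            for i in range(10)
        ]
        wave = rp.build_waveform(tracks, fps)
        ref = (s - s.mean()) / s.std()
        # Interior comparison: the moving-average detrend has edge
        # transients in the first/last detrending window.
        corr = np.corrcoef(wave.samples[30:-30], ref[30:-30])[0, 1]
        assert abs(corr) > 0.999
        assert np.std(wave.samples) == pytest.approx(1.0, rel=0.15)
        assert abs(wave.samples.mean()) < 1e-9 * wave.samples.std()

    def test_single_noise_track_is_voted_down(self, rng):
        fps = 30.0
        t = np.arange(600) / fps
        s = np.sin(2 * np.pi * 2.5 * t)
        tracks = [
            make_track(i, np.column_stack([100 + 2 * s, np.full_like(s, 60.0 + i)]))
            for i in range(9)
        ]
        noise = rng.standard_normal((600, 2)) * 2.0 + [100, 80]
        tracks.append(make_track(9, noise))
        wave = rp.build_waveform(tracks, fps)
        corr = np.corrcoef(wave.samples, s)[0, 1]
        assert abs(corr) > 0.99

    def test_opposite_phase_tracks_are_sign_aligned(self):
        fps = 30.0
        t = np.arange(450) / fps
        s = np.sin(2 * np.pi * 2.0 * t)
        up = [make_track(i, np.column_stack([100 + 2 * s, 50 + 0 * s])) for i in range(5)]
        down = [make_track(5 + i, np.column_stack([200 - 2 * s, 80 + 0 * s])) for i in range(5)]
        wave = rp.build_waveform(up + down, fps)
        assert abs(np.corrcoef(wave.samples, s)[0, 1]) > 0.99

    def test_insufficient_coverage_raises(self):
        valid = np.zeros(100, bool)
        valid[:30] = True  # only 30% coverage
        t = make_track(0, np.random.default_rng(0).normal(size=(100, 2)), valid)
        with pytest.raises(ValueError, match="no track"):
            rp.build_waveform([t], 30.0)


class TestEstimateRate:
    def test_pure_sine_within_half_bpm(self):
        est = rp.estimate_rate(make_sine_signal(150.0))
        assert est.rate_bpm == pytest.approx(150.0, abs=0.5)
        assert est.qc_pass

    def test_realistic_clip_within_5_bpm(self, standard_clip, standard_scenario):
        seq, truth = standard_clip
        est = rp.estimate_rate_from_clip(seq, [rp.RoiContour(sv.flank_roi(standard_scenario))])
        assert est.qc_pass
        assert abs(est.rate_bpm - truth.true_rate_bpm) <= 5.0

    def test_pause_event_fails_qc(self):
        sc = sv.BreathingScenario(
            rate_bpm=180.0, duration_s=12.0, seed=17, events=(("pause", 4.0, 4.0),)
        )
        seq, _ = sv.render_breathing_clip(sc)
        est = rp.estimate_rate_from_clip(seq, [rp.RoiContour(sv.flank_roi(sc))])
        assert not est.qc_pass

    def test_too_short_signal_rejected(self):
        sig = rp.RespirationSignal(np.sin(np.arange(30)), fps=30.0)
        with pytest.raises(ValueError, match="2 seconds"):
            rp.estimate_rate(sig)

    def test_scale_invariance(self):
        # Amplitude depends on camera distance; frequency must not.
        sig = make_sine_signal(137.0)
        base = rp.estimate_rate(sig).rate_bpm
        for scale in (0.01, 3.7, 1000.0):
            scaled = rp.RespirationSignal(sig.samples * scale, sig.fps)
            assert rp.estimate_rate(scaled).rate_bpm == pytest.approx(base, abs=1e-9)

    def test_rotation_invariance(self, clean_clip, clean_scenario):
        seq, truth = clean_clip
        h = clean_scenario.frame_shape[0]
        rot_frames = np.stack([np.rot90(f) for f in seq.frames])
        rot_seq = FrameSequence(rot_frames, seq.fps)
        verts = sv.flank_roi(clean_scenario)
        rot_verts = np.column_stack([h - 1 - verts[:, 1], verts[:, 0]])
        est = rp.estimate_rate_from_clip(rot_seq, [rp.RoiContour(rot_verts)])
        base = rp.estimate_rate_from_clip(seq, [rp.RoiContour(verts)])
        assert est.rate_bpm == pytest.approx(base.rate_bpm, abs=0.5)

    def test_error_bounded_by_resolution_and_shrinks_with_duration(self):
        rate = 157.3  # deliberately off any FFT bin
        errors = []
        for dur in (5.0, 10.0, 20.0):
            est = rp.estimate_rate(make_sine_signal(rate, duration_s=dur))
            err = abs(est.rate_bpm - rate)
            assert err <= 60.0 / dur  # interpolated-FFT resolution bound
            errors.append(err)
        assert errors[2] <= errors[0]

    def test_oracle_equivalence_with_ground_truth_series(
        self, clean_clip, clean_scenario, clean_tracks
    ):
        # The pipeline rate must agree with the rate taken directly from
        # the generator's displacement series.
        seq, truth = clean_clip
        wave = rp.build_waveform(clean_tracks, seq.fps)
        pipeline = rp.estimate_rate(wave).rate_bpm
        proj = truth.displacement_series @ clean_scenario.axis_unit
        direct = rp.estimate_rate(rp.RespirationSignal(proj - proj.mean(), seq.fps)).rate_bpm
        assert pipeline == pytest.approx(direct, abs=1.0)


class TestSummarizeAndValidate:
    @staticmethod
    def _est(rate, qc=True):
        return rp.RateEstimate(rate, (60, 400), 10.0, 0.05, 10, qc)

    def test_median_of_passing_clips(self):
        res = rp.summarize_mouse([self._est(r) for r in (150, 152, 148, 151, 149)])
        assert res.summary_bpm == 150
        assert res.n_clips == 5

    def test_failing_clip_excluded_with_warning(self):
        ests = [self._est(r) for r in (150, 152, 148, 151)] + [self._est(400, qc=False)]
        with pytest.warns(UserWarning, match="QC-passing"):
            res = rp.summarize_mouse(ests)
        assert res.summary_bpm == pytest.approx(150.5)
        assert res.n_clips == 4

    def test_all_failing_raises(self):
        with pytest.raises(ValueError, match="no clip passed"):
            rp.summarize_mouse([self._est(150, qc=False)])

    def test_agreement_fraction(self):
        pairs = [(150, 152), (148, 148), (160, 170)]
        assert rp.validate_against_reference(pairs) == pytest.approx(2 / 3)
        assert rp.validate_against_reference([(150, 150)] * 5) == 1.0
        with pytest.raises(ValueError):
            rp.validate_against_reference([])


class TestAutoRoi:
    def test_auto_roi_finds_the_breathing_flank(self, standard_clip, standard_scenario):
        seq, truth = standard_clip
        roi = rp.auto_roi(seq)
        est = rp.estimate_rate_from_clip(seq, [roi])
        assert abs(est.rate_bpm - truth.true_rate_bpm) <= 5.0
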