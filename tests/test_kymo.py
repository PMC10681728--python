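"""Kymograph extraction, tracking, motion classification, kinematics."""

import numpy as np
import pytest

from curtainkit import simgen
from curtainkit.config import ImagingConfig
from curtainkit.kymo import (
    Kymograph,
    TranslocationTrack,
    UndefinedKinematicsError,
    classify_motion,
    compute_track_length,
    compute_velocity,
    extract_kymograph,
    track_particle,
)


def _track(positions, frame_interval=0.4):
    positions = np.asarray(positions, dtype=float)
    return TranslocationTrack(
        positions=positions, times=np.arange(positions.size) * frame_interval
    )


class TestExtraction:
    CFG = ImagingConfig.two_color(frames=10, shape=(8, 32))

    def test_repeated_profile_gives_identical_rows(self):
        profile = np.arange(32, dtype=float)
        stack = np.tile(profile, (10, 8, 1))
        roi = np.stack([np.full(32, 4), np.arange(32)], axis=1)
        kymo = extract_kymograph(stack, roi, self.CFG)
        assert np.array_equal(kymo.data, np.tile(profile, (10, 1)))

    def test_moving_bright_pixel_traces_a_diagonal(self):
        stack = np.zeros((10, 8, 32))
        for t in range(10):
            stack[t, 4, t] = 1.0
        roi = np.stack([np.full(32, 4), np.arange(32)], axis=1)
        kymo = extract_kymograph(stack, roi, self.CFG)
        assert np.array_equal(kymo.data.argmax(axis=1), np.arange(10))

    def test_roi_outside_image_rejected(self):
        stack = np.zeros((5, 8, 32))
        roi = np.stack([np.full(40, 4), np.arange(40)], axis=1)
        with pytest.raises(ValueError, match="outside"):
            extract_kymograph(stack, roi, self.CFG)


class TestTracking:
    CFG = ImagingConfig.two_color(frames=200, shape=(16, 128))

    def _render(self, positions, noise_sd=0.0, seed=0):
        track = _track(positions)
        return simgen.render_kymograph(
            [track], psf_sd=1.2, noise_sd=noise_sd, background=10.0,
            config=self.CFG, seed=seed,
        )

    def test_stationary_ridge_tracked_at_constant_position(self):
        kymo = self._render(np.full(self.CFG.frames, 40.0))
        trk = track_particle(kymo, start_hint=40.0)
        assert np.allclose(trk.positions, 40.0, atol=1e-6)

    def test_linear_mover_slope_recovered_subpixel(self):
        pos = 20.0 + 0.05 * np.arange(self.CFG.frames)
        trk = track_particle(self._render(pos), start_hint=20.0)
        slope = np.polyfit(np.arange(trk.n_frames), trk.positions, 1)[0]
        assert slope == pytest.approx(0.05, abs=0.001)

    def test_noisy_track_rms_error_bounded(self):
        pos = 20.0 + 0.05 * np.arange(self.CFG.frames)
        # SNR 5: peak amplitude 500, noise 100
        track = _track(pos)
        kymo = simgen.render_kymograph(
            [track], psf_sd=1.2, noise_sd=100.0, background=10.0,
            config=self.CFG, seed=8, amplitudes=[500.0],
        )
        trk = track_particle(kymo, start_hint=20.0)
        rms = np.sqrt(np.mean((trk.positions - pos[: trk.n_frames]) ** 2))
        assert rms <= 0.5

    def test_missing_signal_at_start_rejected(self):
        kymo = self._render(np.full(self.CFG.frames, 40.0))
        with pytest.raises(ValueError, match="no signal"):
            track_particle(kymo, start_hint=100.0)

    def test_window_too_small_rejected(self):
        kymo = self._render(np.full(self.CFG.frames, 40.0))
        with pytest.raises(ValueError, match="window"):
            track_particle(kymo, start_hint=40.0, window=2)


class TestClassification:
    def test_fully_static_track_is_all_pre_start(self):
        segs = classify_motion(_track(np.full(40, 10.0)))
        assert [s.label for s in segs] == ["pre_start"]
        assert (segs[0].start, segs[0].stop) == (0, 40)

    def test_pause_of_three_frames_labeled_paused(self):
        # move 5 px, stall 3 frames, move on: pre-start / transloc / paused / transloc
        pos = [0, 1, 2, 3, 4, 5, 5, 5, 5, 6, 7, 8]
        track = _track(pos)
        segs = classify_motion(track)
        assert [s.label for s in segs] == [
            "pre_start", "translocating", "paused", "translocating",
        ]
        paused = segs[2]
        assert paused.stop - paused.start == 3

    def test_long_stall_terminates_track(self):
        pos = [0, 1, 2, 3, 4, 5] + [5] * 12
        track = _track(pos)
        segs = classify_motion(track)
        assert segs[-1].label == "terminated"
        assert segs[-1].start == 6
        assert track.termination_frame == 6

    def test_intermediate_stall_is_labeled_stall_not_terminated(self):
        pos = [0, 1, 2, 3, 4, 5] + [5] * 7 + [6, 7, 8]
        segs = classify_motion(_track(pos))
        labels = [s.label for s in segs]
        assert "stall" in labels and "terminated" not in labels

    def test_segments_partition_frames(self):
        pos = [0, 1, 2, 3, 4, 5, 5, 5, 5, 6, 7] + [7] * 14
        track = _track(pos)
        segs = classify_motion(track)
        covered = sorted(
            frame for s in segs for frame in range(s.start, s.stop)
        )
        assert covered == list(range(len(pos)))

    def test_classification_invariant_to_intensity_scaling(self):
        cfg = ImagingConfig.two_color(frames=60, shape=(16, 64))
        pos = np.concatenate([20 + 0.5 * np.arange(40), np.full(20, 39.5)])
        track = _track(pos)
        kymo = simgen.render_kymograph(
            [track], psf_sd=1.2, noise_sd=0.0, background=10.0, config=cfg, seed=0
        )
        trk1 = track_particle(kymo, start_hint=20.0)
        scaled = Kymograph(
            data=kymo.data * 37.0,
            frame_interval=kymo.frame_interval,
            bp_per_pixel=kymo.bp_per_pixel,
        )
        trk2 = track_particle(scaled, start_hint=20.0)
        labels1 = [s.label for s in classify_motion(trk1)]
        labels2 = [s.label for s in classify_motion(trk2)]
        assert labels1 == labels2


class TestKinematics:
    CFG = ImagingConfig(
        frame_integration=10.0, inter_frame_delay=0.0, bp_per_pixel=1000.0, frames=30
    )

    def test_hand_computed_velocity(self):
        # 1 px / 10 s after the 2-px start: 7 px over 70 s -> 100 bp/s
        pos = list(range(11)) + [10] * 12
        track = _track(pos, frame_interval=10.0)
        classify_motion(track)
        assert compute_velocity(track, self.CFG) == pytest.approx(100.0)

    def test_track_length_in_kb(self):
        pos = list(range(11)) + [10] * 12
        track = _track(pos, frame_interval=10.0)
        classify_motion(track)
        # start frame at disp > 2 px (frame 3, pos 3); end at pos 10 -> 7 px
        assert compute_track_length(track, self.CFG) == pytest.approx(7.0)

    def test_static_track_has_undefined_velocity(self):
        track = _track(np.full(30, 4.0))
        classify_motion(track)
        with pytest.raises(UndefinedKinematicsError):
            compute_velocity(track, self.CFG)

    def test_velocity_times_elapsed_equals_length(self):
        """velocity * elapsed time == track length * 1000 for every track."""
        cfg = ImagingConfig.two_color(frames=800, shape=(16, 256))
        for seed in range(20):
            track, _ = simgen.simulate_translocation_track(
                90.0, 40.0, 0.05, (2, 4), 0.004, cfg, seed=seed
            )
            classify_motion(track)
            try:
                v = compute_velocity(track, cfg)
                length = compute_track_length(track, cfg)
            except UndefinedKinematicsError:
                continue
            start, term = track.start_frame, track.termination_frame
            end = term - 1 if term is not None else track.n_frames - 1
            elapsed = track.times[end] - track.times[start]
            assert v * elapsed == pytest.approx(length * 1000.0, rel=1e-9)

    def test_noiseless_linear_mover_velocity_exact(self):
        """Rendered, re-tracked noiseless movers recover velocity to 0.1%."""
        cfg = ImagingConfig.two_color(frames=300, shape=(16, 128))
        v_true = 100.0  # 0.04 px/frame
        pos = np.minimum(20.0 + 0.04 * np.arange(cfg.frames), 127.0)
        track = _track(pos)
        kymo = simgen.render_kymograph(
            [track], psf_sd=1.2, noise_sd=0.0, background=10.0, config=cfg, seed=0
        )
        trk = track_particle(kymo, start_hint=20.0)
        classify_motion(trk)
        v = compute_velocity(trk, cfg)
        assert v == pytest.approx(v_true, rel=1e-3)
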