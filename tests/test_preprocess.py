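"""Channel selection, standardization, pelvic filtering, sampling."""

from __future__ import annotations

import numpy as np
import pytest

import gaitlatent as gl
from gaitlatent.channels import analysis_schema, full_schema
from gaitlatent.preprocess import (
    DegenerateChannelError,
    MissingPelvicTraceError,
)
from gaitlatent.recording import KinematicRecording, SchemaError


def _recording(angles, pelvic=None, activity="flat", schema=None, subject="X00"):
    schema = schema or full_schema()
    return KinematicRecording(
        subject_id=subject,
        activity=activity,
        rate=60.0,
        schema=schema,
        angles=angles,
        pelvic_speed=pelvic,
    )


class TestChannelSelection:
    def test_drops_knee_frontal_and_transverse(self, flat_profile):
        rec = gl.generate_recording(flat_profile, "flat", duration=1.0, seed=0)
        out = gl.select_channels(rec)
        assert out.angles.shape[1] == 14
        names = out.schema.names
        assert "knee_left_frontal" not in names
        assert "knee_right_transverse" not in names
        assert "knee_left_sagittal" in names

    def test_idempotent(self, flat_profile):
        rec = gl.generate_recording(flat_profile, "flat", duration=1.0, seed=0)
        once = gl.select_channels(rec)
        twice = gl.select_channels(once)
        assert twice.schema.names == once.schema.names
        np.testing.assert_array_equal(twice.angles, once.angles)

    def test_sentinel_values_in_dropped_channels_vanish(self):
        schema = full_schema()
        angles = np.zeros((10, 18))
        sentinel = 999.0
        for i, ch in enumerate(schema):
            if ch.joint == "knee" and ch.plane != "sagittal":
                angles[:, i] = sentinel
        out = gl.select_channels(_recording(angles))
        assert not np.any(out.angles == sentinel)

    def test_missing_channel_raises(self):
        partial = gl.ChannelSchema(full_schema().channels[:10])
        rec = _recording(np.zeros((5, 10)), schema=partial)
        with pytest.raises(SchemaError):
            gl.select_channels(rec)


class TestStandardizer:
    def test_symmetric_constant_recordings(self):
        schema = analysis_schema()
        up = _recording(np.ones((50, 14)), schema=schema)
        down = _recording(-np.ones((50, 14)), schema=schema)
        std = gl.fit_standardizer([up, down])
        np.testing.assert_allclose(std.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(std.scale, 1.0, atol=1e-12)

    def test_single_recording_self_zscore(self, flat_profile):
        rec = gl.select_channels(
            gl.generate_recording(flat_profile, "flat", duration=5.0, seed=0)
        )
        std = gl.fit_standardizer([rec])
        z = std.transform(rec.angles)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_matches_concatenate_then_moments_oracle(self, small_dataset):
        recs = [gl.select_channels(r) for r in small_dataset.recordings]
        std = gl.fit_standardizer(recs)
        pooled = np.concatenate([r.angles for r in recs], axis=0)
        np.testing.assert_allclose(std.mean, pooled.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(std.scale, pooled.std(axis=0), atol=1e-12)

    def test_transform_inverse_round_trip(self, small_dataset):
        recs = [gl.select_channels(r) for r in small_dataset.recordings]
        std = gl.fit_standardizer(recs)
        x = recs[0].angles
        np.testing.assert_allclose(std.inverse(std.transform(x)), x, atol=1e-9)

    def test_degenerate_channel_rejected(self):
        rec = _recording(np.zeros((10, 14)), schema=analysis_schema())
        with pytest.raises(DegenerateChannelError):
            gl.fit_standardizer([rec])


class TestPelvicFilter:
    def _rec_with_trace(self, trace):
        n = len(trace)
        return _recording(
            np.random.default_rng(0).normal(size=(n, 14)),
            pelvic=np.asarray(trace, dtype=float),
            schema=analysis_schema(),
            activity="natural",
        )

    def test_all_idle_empty(self):
        rec = self._rec_with_trace(np.zeros(200))
        assert gl.filter_by_pelvic_velocity(rec, threshold=0.1) == []

    def test_all_active_single_full_segment(self):
        rec = self._rec_with_trace(np.ones(200))
        segments = gl.filter_by_pelvic_velocity(rec, threshold=0.1)
        assert len(segments) == 1
        assert segments[0].n_frames == 200

    def test_run_length_oracle(self):
        trace = np.concatenate([np.zeros(100), np.ones(200), np.zeros(100)])
        rec = self._rec_with_trace(trace)
        segments = gl.filter_by_pelvic_velocity(rec, threshold=0.1, min_segment=60)
        assert len(segments) == 1
        assert segments[0].n_frames == 200
        assert segments[0].start_frame == 100

    def test_short_bursts_discarded(self):
        trace = np.concatenate([np.ones(30), np.zeros(50), np.ones(100)])
        rec = self._rec_with_trace(trace)
        segments = gl.filter_by_pelvic_velocity(rec, threshold=0.5, min_segment=60)
        assert [s.n_frames for s in segments] == [100]

    def test_missing_trace_raises(self):
        rec = _recording(np.zeros((10, 14)) + np.arange(14), schema=analysis_schema())
        with pytest.raises(MissingPelvicTraceError):
            gl.filter_by_pelvic_velocity(rec, threshold=0.1)


@pytest.fixture(scope="module")
def std(small_dataset):
    recs = [gl.select_channels(r) for r in small_dataset.recordings]
    return gl.fit_standardizer(recs)


class TestSampling:
    def _flat_rec(self, small_dataset, n_frames):
        rec = gl.select_channels(small_dataset.recordings[0])
        return rec.slice(0, n_frames)

    @pytest.mark.parametrize(
        "n_frames,stride,expected",
        [(600, 10, 60), (5, 10, 1), (601, 10, 61)],
    )
    def test_pose_counts(self, small_dataset, std, n_frames, stride, expected):
        rec = self._flat_rec(small_dataset, n_frames)
        assert len(gl.sample_poses(rec, std, stride)) == expected

    @pytest.mark.parametrize(
        "n_frames,expected", [(600, 55), (60, 1), (59, 0)]
    )
    def test_window_counts(self, small_dataset, std, n_frames, expected):
        rec = self._flat_rec(small_dataset, n_frames)
        assert len(gl.sample_windows(rec, std, window=60, stride=10)) == expected

    def test_pose_inverse_standardize_recovers_frame(self, small_dataset, std):
        rec = self._flat_rec(small_dataset, 600)
        poses = gl.sample_poses(rec, std, stride=10)
        for p in poses[:5]:
            np.testing.assert_allclose(
                std.inverse(p.values), rec.angles[p.frame], atol=1e-9
            )

    def test_window_rows_equal_pose_samples(self, small_dataset, std):
        """Row r of any window equals the pose sampled at its frame, so
        pose-level and movement-level reducers see consistent data."""
        rec = self._flat_rec(small_dataset, 600)
        windows = gl.sample_windows(rec, std, window=60, stride=10)
        z = std.transform(rec.angles)
        for w in windows[:5]:
            np.testing.assert_allclose(
                w.values, z[w.start_frame : w.start_frame + 60], atol=1e-12
            )

    def test_windows_do_not_cross_recording_boundaries(self, small_study):
        """Every window's 60 frames belong to a single subject recording."""
        starts = small_study.win_start
        assert np.all(starts >= 0)
        # windows sampled per recording: start+60 never exceeds that
        # recording's frame count (20 s * 60 Hz = 1200 frames)
        assert np.all((starts % 1200) + 60 <= 1200)
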