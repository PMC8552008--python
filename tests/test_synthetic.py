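"""Synthetic gait generator: determinism, periodicity, structure."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import gaitlatent as gl
from gaitlatent.synthetic import UnknownTemplateError, default_template


class TestProfiles:
    def test_same_inputs_same_profile(self):
        a = gl.make_profile("flat", 0, seed=42)
        b = gl.make_profile("flat", 0, seed=42)
        assert a.cadence == b.cadence
        np.testing.assert_array_equal(a.amplitude, b.amplitude)
        np.testing.assert_array_equal(a.offset, b.offset)
        np.testing.assert_array_equal(a.phase, b.phase)

    def test_distinct_subjects_distinct_profiles(self):
        a = gl.make_profile("flat", 0, seed=42)
        b = gl.make_profile("flat", 1, seed=42)
        assert np.any(a.amplitude != b.amplitude)

    def test_unknown_template_rejected(self):
        with pytest.raises(UnknownTemplateError):
            gl.make_profile("jogging", 0, seed=1)

    def test_negative_subject_index_rejected(self):
        with pytest.raises(ValueError):
            gl.make_profile("flat", -1, seed=1)

    def test_eight_subjects_pairwise_distinct_mean_poses(self):
        """Noise-free mean poses of 8 subjects are pairwise separated."""
        means = []
        for idx in range(8):
            profile = dataclasses.replace(
                gl.make_profile("flat", idx, seed=42), noise_sd=0.0
            )
            rec = gl.generate_recording(profile, "flat", duration=10.0, seed=0)
            means.append(rec.angles.mean(axis=0))
        means = np.stack(means)
        for i in range(8):
            for j in range(i + 1, 8):
                assert np.linalg.norm(means[i] - means[j]) > 0

    def test_cadence_snaps_to_integer_period(self):
        profile = gl.make_profile("stair", 3, seed=9)
        period = 60.0 / profile.cadence
        assert abs(period - round(period)) < 1e-9


class TestRecordings:
    def test_shape_and_pelvic_trace(self, flat_profile):
        rec = gl.generate_recording(flat_profile, "flat", duration=4.0, seed=0)
        assert rec.angles.shape == (240, 18)
        assert rec.pelvic_speed.shape == (240,)

    def test_noise_free_exact_periodicity(self, noise_free_flat, flat_profile):
        period = flat_profile.period_frames(60.0)
        x = noise_free_flat.angles
        np.testing.assert_allclose(x[:-period], x[period:], atol=1e-9)

    def test_zero_amplitude_gives_static_offset(self, flat_profile):
        profile = dataclasses.replace(
            flat_profile,
            amplitude=np.zeros(18),
            noise_sd=0.0,
        )
        rec = gl.generate_recording(profile, "flat", duration=2.0, seed=0)
        np.testing.assert_allclose(
            rec.angles,
            np.broadcast_to(profile.offset, rec.angles.shape),
            atol=1e-12,
        )

    def test_noise_sd_matches_residual_sd(self, flat_profile):
        noisy = dataclasses.replace(flat_profile, noise_sd=2.0)
        clean = dataclasses.replace(flat_profile, noise_sd=0.0)
        duration = 10000 / 60.0
        a = gl.generate_recording(noisy, "flat", duration=duration, seed=3)
        b = gl.generate_recording(clean, "flat", duration=duration, seed=3)
        residual_sd = (a.angles - b.angles).std(axis=0)
        assert np.all(residual_sd > 1.8) and np.all(residual_sd < 2.2)

    def test_invalid_duration_and_rate_rejected(self, flat_profile):
        with pytest.raises(ValueError):
            gl.generate_recording(flat_profile, "flat", duration=0.0, seed=0)
        with pytest.raises(ValueError):
            gl.generate_recording(flat_profile, "flat", duration=1.0, rate=0, seed=0)

    def test_time_reversal_is_not_a_phase_shift(self, noise_free_flat, flat_profile):
        """With >=2 harmonics at generic phases, a reversed cycle cannot be
        matched by any circular shift of the forward cycle."""
        period = flat_profile.period_frames(60.0)
        cycle = noise_free_flat.angles[:period]
        reversed_cycle = cycle[::-1]
        mismatch = min(
            np.abs(np.roll(reversed_cycle, s, axis=0) - cycle).max()
            for s in range(period)
        )
        assert mismatch > 1e-9


class TestStudy:
    def test_counts_and_unique_ids(self):
        ds = gl.generate_study(8, 11, 13, duration=2.0, seed=7)
        assert len(ds.recordings) == 32
        ids = [r.subject_id for r in ds.recordings]
        assert len(set(ids)) == 32

    def test_single_natural_subject(self):
        ds = gl.generate_study(0, 0, 1, duration=10.0, seed=7)
        assert len(ds.recordings) == 1
        assert ds.recordings[0].activity == "natural"

    def test_seed_determinism_bitwise(self):
        a = gl.generate_study(2, 2, 0, duration=5.0, seed=7)
        b = gl.generate_study(2, 2, 0, duration=5.0, seed=7)
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.angles, rb.angles)
            np.testing.assert_array_equal(ra.pelvic_speed, rb.pelvic_speed)

    def test_class_separation_exceeds_noise(self):
        """Flat vs stair per-channel means differ by >=1 noise SD on >=4
        channels, so class structure survives the sensor noise."""
        ds = gl.generate_study(4, 4, 0, duration=20.0, seed=3)
        flat = np.concatenate([r.angles for r in ds.by_activity("flat")])
        stair = np.concatenate([r.angles for r in ds.by_activity("stair")])
        gap = np.abs(flat.mean(axis=0) - stair.mean(axis=0))
        noise_sd = ds.templates["flat"].noise_sd
        assert np.sum(gap >= noise_sd) >= 4

    def test_natural_idle_segments_have_zero_pelvic_speed(self):
        ds = gl.generate_study(0, 0, 2, duration=60.0, seed=5)
        for rec in ds.recordings:
            assert np.any(rec.pelvic_speed == 0.0), "no idle frames generated"
            assert np.any(rec.pelvic_speed > 0.5), "no active frames generated"


class TestRoundTrip:
    def test_csv_sidecar_round_trip(self, tmp_path, flat_profile):
        rec = gl.generate_recording(flat_profile, "flat", duration=2.0, seed=1)
        gl.write_recording(rec, tmp_path)
        back = gl.read_study(tmp_path)[0]
        assert back.subject_id == rec.subject_id
        assert back.activity == rec.activity
        assert back.schema.names == rec.schema.names
        np.testing.assert_allclose(back.angles, rec.angles, atol=1e-8)
        np.testing.assert_allclose(back.pelvic_speed, rec.pelvic_speed, atol=1e-8)
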