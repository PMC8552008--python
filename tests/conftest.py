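"""Shared fixtures: small synthetic studies and preprocessed samples.

Session-scoped so expensive generation happens once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import gaitlatent as gl


@pytest.fixture(scope="session")
def small_dataset() -> gl.SyntheticDataset:
    """2 flat + 2 stair + 1 natural subjects, 20 s each."""
    return gl.generate_study(2, 2, 1, duration=20.0, seed=7)


@pytest.fixture(scope="session")
def small_study(small_dataset) -> gl.PreparedStudy:
    return gl.prepare_study(small_dataset)


@pytest.fixture(scope="session")
def flat_profile() -> gl.GaitProfile:
    return gl.make_profile("flat", 0, seed=42)


@pytest.fixture(scope="session")
def noise_free_flat(flat_profile) -> gl.KinematicRecording:
    """4 s of exactly periodic flat-ground gait (no sensor noise)."""
    import dataclasses

    profile = dataclasses.replace(flat_profile, noise_sd=0.0)
    return gl.generate_recording(profile, "flat", duration=4.0, seed=0)


@pytest.fixture(scope="session")
def pose_matrix(small_study) -> np.ndarray:
    return small_study.pose_x
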