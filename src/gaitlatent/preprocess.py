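"""Channel selection, standardization, activity filtering, and sampling.

Raw recordings are reduced to the 14 analysis channels (knee frontal and
transverse planes dropped), z-scored with per-channel statistics pooled over
*all* recordings of all activity classes, filtered by pelvic speed when they
come from an unscripted natural stream, and finally sampled into single
poses (1 x 14) or one-second movement windows (60 x 14) on a fixed frame
stride (default 10 frames at 60 Hz, i.e. one sample every 1/6 s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .channels import ChannelSchema, analysis_schema
from .recording import KinematicRecording, SchemaError

DEFAULT_STRIDE = 10  # frames; 10/60 s between consecutive samples
DEFAULT_WINDOW = 60  # frames; one second at 60 Hz


class DegenerateChannelError(ValueError):
    """A channel has zero pooled variance and cannot be standardized."""


class MissingPelvicTraceError(ValueError):
    """Pelvic-speed filtering was requested on a recording without a trace."""


def select_channels(recording: KinematicRecording) -> KinematicRecording:
    """Reduce to the 14-channel analysis schema. Idempotent."""
    target = analysis_schema()
    if recording.schema.names == target.names:
        return recording
    indices = []
    for ch in target:
        try:
            indices.append(recording.schema.index(ch))
        except ValueError:
            raise SchemaError(f"recording lacks required channel {ch.name}") from None
    return replace(
        recording,
        schema=target,
        angles=recording.angles[:, indices].copy(),
    )


@dataclass
class Standardizer:
    """Per-channel location/scale from the pooled frames of all datasets."""

    mean: np.ndarray  # (channels,)
    scale: np.ndarray  # (channels,), > 0
    schema: ChannelSchema

    def transform(self, angles: np.ndarray) -> np.ndarray:
        return (angles - self.mean) / self.scale

    def inverse(self, standardized: np.ndarray) -> np.ndarray:
        return standardized * self.scale + self.mean


def fit_standardizer(recordings: list[KinematicRecording]) -> Standardizer:
    """Pooled per-channel mean and SD over all frames of all recordings.

    Population (ddof=0) statistics; all activity classes are pooled so every
    reducer sees the same standardized units.
    """
    if not recordings:
        raise ValueError("no recordings to fit on")
    schema = recordings[0].schema
    for rec in recordings[1:]:
        if rec.schema.names != schema.names:
            raise SchemaError("recordings have mismatched channel schemas")
    stacked = np.concatenate([rec.angles for rec in recordings], axis=0)
    if stacked.shape[0] < 2:
        raise ValueError("need at least 2 pooled frames per channel")
    mean = stacked.mean(axis=0)
    scale = stacked.std(axis=0)
    bad = np.flatnonzero(scale <= 0)
    if bad.size:
        names = [schema.names[i] for i in bad]
        raise DegenerateChannelError(f"zero pooled variance in channels {names}")
    return Standardizer(mean=mean, scale=scale, schema=schema)


def filter_by_pelvic_velocity(
    recording: KinematicRecording,
    threshold: float | None = None,
    min_segment: int = DEFAULT_WINDOW,
) -> list[KinematicRecording]:
    """Contiguous sub-recordings where the pelvis is actually moving.

    Keeps maximal runs of frames with pelvic speed >= ``threshold`` lasting
    at least ``min_segment`` frames.  With ``threshold=None`` it defaults to
    10% of the median positive pelvic speed, a scale-free choice that stays
    well below any walking bout yet above the (zero) idle floor.
    """
    if recording.pelvic_speed is None:
        raise MissingPelvicTraceError(
            f"recording {recording.subject_id} has no pelvic-speed trace"
        )
    trace = recording.pelvic_speed
    if threshold is None:
        positive = trace[trace > 0]
        if positive.size == 0:
            return []
        threshold = 0.1 * float(np.median(positive))
    active = trace >= threshold
    segments: list[KinematicRecording] = []
    # run-length scan over the boolean activity mask
    edges = np.flatnonzero(np.diff(active.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    stops = np.concatenate((edges + 1, [active.size]))
    for start, stop in zip(starts, stops):
        if active[start] and stop - start >= min_segment:
            segments.append(recording.slice(start, stop))
    return segments


@dataclass
class PoseSample:
    """A single standardized 14-channel pose with provenance."""

    values: np.ndarray  # (14,)
    subject_id: str
    activity: str
    frame: int  # frame index in the source stream

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(analysis_schema()),):
            raise ValueError("pose must have exactly 14 entries")


@dataclass
class MovementWindow:
    """One second of consecutive standardized poses (60 x 14)."""

    values: np.ndarray  # (60, 14)
    subject_id: str
    activity: str
    start_frame: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(analysis_schema()):
            raise ValueError("window must be frames x 14")


def sample_poses(
    recording: KinematicRecording,
    standardizer: Standardizer,
    stride: int = DEFAULT_STRIDE,
) -> list[PoseSample]:
    """Standardized poses at frames 0, stride, 2*stride, ..."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    z = standardizer.transform(recording.angles)
    return [
        PoseSample(
            values=z[i],
            subject_id=recording.subject_id,
            activity=recording.activity,
            frame=recording.start_frame + i,
        )
        for i in range(0, recording.n_frames, stride)
    ]


def sample_windows(
    recording: KinematicRecording,
    standardizer: Standardizer,
    window: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
) -> list[MovementWindow]:
    """Overlapping standardized windows starting every ``stride`` frames.

    A recording shorter than ``window`` yields an empty list.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if window < 2:
        raise ValueError("window must be >= 2")
    z = standardizer.transform(recording.angles)
    return [
        MovementWindow(
            values=z[s : s + window],
            subject_id=recording.subject_id,
            activity=recording.activity,
            start_frame=recording.start_frame + s,
        )
        for s in range(0, recording.n_frames - window + 1, stride)
    ]


def stack_poses(poses: list[PoseSample]) -> np.ndarray:
    """(n, 14) matrix from a list of pose samples."""
    return np.stack([p.values for p in poses], axis=0)


def stack_windows(windows: list[MovementWindow]) -> np.ndarray:
    """(n, 60, 14) tensor from a list of movement windows."""
    return np.stack([w.values for w in windows], axis=0)
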