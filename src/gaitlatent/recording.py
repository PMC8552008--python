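"""Kinematic recordings and their on-disk CSV + JSON sidecar format.

A :class:`KinematicRecording` is one subject performing one activity: a
frames x channels matrix of joint angles in degrees sampled at a fixed rate
(60 Hz by default), plus an optional pelvic-speed trace used to filter
inactivity out of unscripted "natural" streams.

On disk a recording is a CSV with one header row (channel names followed by
``pelvic_speed`` when present) and one row per frame, next to a ``.meta.json``
sidecar carrying subject id, activity label, rate and generation provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import ChannelSchema

ACTIVITIES = ("flat", "stair", "natural")


class SchemaError(ValueError):
    """Channel schema does not match the data or a required channel is missing."""


@dataclass
class KinematicRecording:
    subject_id: str
    activity: str
    rate: float
    schema: ChannelSchema
    angles: np.ndarray  # (frames, channels), degrees
    pelvic_speed: np.ndarray | None = None  # (frames,), arbitrary speed units
    start_frame: int = 0  # offset into the source stream (set by filtering)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be a 2-D frames x channels array")
        if self.angles.shape[1] != len(self.schema):
            raise SchemaError(
                f"angle matrix has {self.angles.shape[1]} columns but schema "
                f"has {len(self.schema)} channels"
            )
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles contain non-finite values")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.pelvic_speed is not None:
            self.pelvic_speed = np.asarray(self.pelvic_speed, dtype=float)
            if self.pelvic_speed.shape != (self.angles.shape[0],):
                raise ValueError("pelvic_speed length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate

    def slice(self, start: int, stop: int) -> "KinematicRecording":
        """A contiguous sub-recording; frame provenance is preserved."""
        return replace(
            self,
            angles=self.angles[start:stop].copy(),
            pelvic_speed=None
            if self.pelvic_speed is None
            else self.pelvic_speed[start:stop].copy(),
            start_frame=self.start_frame + start,
        )


def write_recording(rec: KinematicRecording, directory: str | Path) -> Path:
    """Write ``<subject>_<activity>.csv`` plus a ``.meta.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.subject_id}_{rec.activity}"
    frame = pd.DataFrame(rec.angles, columns=list(rec.schema.names))
    if rec.pelvic_speed is not None:
        frame["pelvic_speed"] = rec.pelvic_speed
    csv_path = directory / f"{stem}.csv"
    frame.to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "subject_id": rec.subject_id,
        "activity": rec.activity,
        "rate": rec.rate,
        "channels": list(rec.schema.names),
        "start_frame": rec.start_frame,
        "meta": _jsonable(rec.meta),
    }
    (directory / f"{stem}.meta.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(csv_path: str | Path) -> KinematicRecording:
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix("").with_suffix(".meta.json")
    if not sidecar_path.exists():  # "<stem>.csv" -> "<stem>.meta.json"
        sidecar_path = csv_path.parent / (csv_path.stem + ".meta.json")
    sidecar = json.loads(sidecar_path.read_text())
    frame = pd.read_csv(csv_path)
    names = sidecar["channels"]
    missing = [n for n in names if n not in frame.columns]
    if missing:
        raise SchemaError(f"CSV is missing channels {missing}")
    pelvic = frame["pelvic_speed"].to_numpy() if "pelvic_speed" in frame else None
    return KinematicRecording(
        subject_id=sidecar["subject_id"],
        activity=sidecar["activity"],
        rate=float(sidecar["rate"]),
        schema=ChannelSchema.from_names(names),
        angles=frame[names].to_numpy(),
        pelvic_speed=pelvic,
        start_frame=int(sidecar.get("start_frame", 0)),
        meta=sidecar.get("meta", {}),
    )


def read_study(directory: str | Path) -> list[KinematicRecording]:
    """Read every recording CSV in a directory, sorted by filename."""
    return [read_recording(p) for p in sorted(Path(directory).glob("*.csv"))]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
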