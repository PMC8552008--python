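"""Joint-angle channel schema for lower-limb kinematics.

Channels describe Euler joint angles (ZXY sequence, ISB convention, degrees)
for the hip, knee and ankle on both sides, each decomposed into sagittal,
frontal and transverse planes.  The full schema has 18 channels; the analysis
schema drops the knee frontal and transverse planes (which in wearable motion
capture mostly reflect sensor noise rather than physiological motion),
leaving 14.

Channel order is fixed: joints in (hip, knee, ankle), sides in (left, right),
planes in (sagittal, frontal, transverse), nested in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

JOINTS = ("hip", "knee", "ankle")
SIDES = ("left", "right")
PLANES = ("sagittal", "frontal", "transverse")

#: planes retained per joint in the analysis schema
RETAINED_PLANES = {
    "hip": ("sagittal", "frontal", "transverse"),
    "knee": ("sagittal",),
    "ankle": ("sagittal", "frontal", "transverse"),
}


@dataclass(frozen=True)
class Channel:
    """One joint-angle channel: a (joint, side, plane) triple."""

    joint: str
    side: str
    plane: str

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")

    @property
    def name(self) -> str:
        return f"{self.joint}_{self.side}_{self.plane}"

    @classmethod
    def from_name(cls, name: str) -> "Channel":
        joint, side, plane = name.split("_")
        return cls(joint, side, plane)


@dataclass(frozen=True)
class ChannelSchema:
    """An ordered, duplicate-free tuple of channels."""

    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channels in schema")

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self) -> Iterator[Channel]:
        return iter(self.channels)

    def __getitem__(self, i: int) -> Channel:
        return self.channels[i]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    def index(self, channel: Channel) -> int:
        return self.channels.index(channel)

    @classmethod
    def from_names(cls, names: list[str] | tuple[str, ...]) -> "ChannelSchema":
        return cls(tuple(Channel.from_name(n) for n in names))


def full_schema() -> ChannelSchema:
    """The 18-channel recording schema (3 joints x 2 sides x 3 planes)."""
    return ChannelSchema(
        tuple(
            Channel(joint, side, plane)
            for joint in JOINTS
            for side in SIDES
            for plane in PLANES
        )
    )


def analysis_schema() -> ChannelSchema:
    """The 14-channel analysis schema (knee frontal/transverse dropped)."""
    return ChannelSchema(
        tuple(
            Channel(joint, side, plane)
            for joint in JOINTS
            for side in SIDES
            for plane in PLANES
            if plane in RETAINED_PLANES[joint]
        )
    )
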