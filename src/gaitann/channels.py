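"""Canonical sensor-channel layout and the seven-activity code set.

The recording setup places five six-axis IMUs on the waist, both thighs and
both shanks, plus four goniometers on both knees and both ankles.  Only the
channels relevant to forward progression are retained, giving 19 channels:

* waist: accelerometer x, accelerometer y, gyroscope x
* each thigh and shank: accelerometer x, accelerometer z, gyroscope y
* knee and ankle goniometers (left and right): absolute joint angle

This module is the single source of truth for channel names/order and for the
integer activity codes; confusion-matrix row order everywhere follows
``ACTIVITY_NAMES``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

LOCATIONS = (
    "waist",
    "thigh_L",
    "thigh_R",
    "shank_L",
    "shank_R",
    "knee_L",
    "knee_R",
    "ankle_L",
    "ankle_R",
)
MODALITIES = ("accel", "gyro", "gonio")
AXES = ("x", "y", "z", "angle")


@dataclass(frozen=True)
class ChannelSpec:
    """One sensory channel: where it is mounted, what it measures, which axis."""

    name: str
    location: str
    modality: str
    axis: str

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")


def _segment_channels(location: str) -> list[ChannelSpec]:
    return [
        ChannelSpec(f"{location}_accel_x", location, "accel", "x"),
        ChannelSpec(f"{location}_accel_z", location, "accel", "z"),
        ChannelSpec(f"{location}_gyro_y", location, "gyro", "y"),
    ]


CANONICAL_CHANNELS: tuple[ChannelSpec, ...] = tuple(
    [
        ChannelSpec("waist_accel_x", "waist", "accel", "x"),
        ChannelSpec("waist_accel_y", "waist", "accel", "y"),
        ChannelSpec("waist_gyro_x", "waist", "gyro", "x"),
    ]
    + _segment_channels("thigh_L")
    + _segment_channels("thigh_R")
    + _segment_channels("shank_L")
    + _segment_channels("shank_R")
    + [
        ChannelSpec("knee_L_gonio_angle", "knee_L", "gonio", "angle"),
        ChannelSpec("knee_R_gonio_angle", "knee_R", "gonio", "angle"),
        ChannelSpec("ankle_L_gonio_angle", "ankle_L", "gonio", "angle"),
        ChannelSpec("ankle_R_gonio_angle", "ankle_R", "gonio", "angle"),
    ]
)

CANONICAL_CHANNEL_NAMES: tuple[str, ...] = tuple(c.name for c in CANONICAL_CHANNELS)

CHANNEL_SUBSETS: dict[str, tuple[str, ...]] = {
    "all": CANONICAL_CHANNEL_NAMES,
    "imu_only": tuple(
        c.name for c in CANONICAL_CHANNELS if c.modality in ("accel", "gyro")
    ),
    "gonio_only": tuple(c.name for c in CANONICAL_CHANNELS if c.modality == "gonio"),
}


def resolve_channel_subset(subset) -> tuple[str, ...]:
    """Resolve a named subset or an explicit channel-name list to canonical order.

    Explicit lists are reordered to canonical order; unknown names raise
    ``KeyError``.
    """
    if isinstance(subset, str):
        try:
            return CHANNEL_SUBSETS[subset]
        except KeyError:
            raise KeyError(
                f"unknown channel subset {subset!r}; "
                f"known: {sorted(CHANNEL_SUBSETS)} or an explicit name list"
            ) from None
    requested = set(subset)
    unknown = requested - set(CANONICAL_CHANNEL_NAMES)
    if unknown:
        raise KeyError(f"unknown channel names: {sorted(unknown)}")
    return tuple(n for n in CANONICAL_CHANNEL_NAMES if n in requested)


class Activity(IntEnum):
    """The seven activities of daily living, in fixed reporting order."""

    SITTING = 0
    STANDING = 1
    WALKING = 2
    RAMP_ASCENT = 3
    RAMP_DESCENT = 4
    STAIR_ASCENT = 5
    STAIR_DESCENT = 6


ACTIVITY_NAMES: tuple[str, ...] = tuple(a.name.lower() for a in Activity)
N_ACTIVITIES = len(Activity)

_NAME_TO_CODE = {name: Activity(i) for i, name in enumerate(ACTIVITY_NAMES)}


def activity_from_label(label) -> Activity:
    """Parse an activity from its name string or integer code."""
    if isinstance(label, str):
        key = label.strip().lower()
        if key in _NAME_TO_CODE:
            return _NAME_TO_CODE[key]
        if key.lstrip("-").isdigit():
            label = int(key)
        else:
            raise ValueError(f"unknown activity label {label!r}")
    code = int(label)
    if not 0 <= code < N_ACTIVITIES:
        raise ValueError(f"activity code {code} outside 0..{N_ACTIVITIES - 1}")
    return Activity(code)
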