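"""Uniform-superposition frame stitching.

The scanner rides a slide rail at constant speed ``a`` while recording ``f``
frames per second, so frame ``k`` was taken with the sensor displaced by
``k*a/f`` along the travel axis from frame 0.  Each point ``P`` of frame ``k``
is translated by that displacement, ``P' = P + d_k``, and the translated
frames are superposed into one dense block cloud.  No odometry is involved:
the rail's uniform motion *is* the pose model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .cloudio import FrameStream, PointCloud

__all__ = ["RailConfig", "parse_speed", "frame_displacement", "stitch"]

_AXES = {"x": 0, "y": 1, "z": 2}

# accepted rail-speed units, converted to m/s at parse time
_SPEED_UNITS = {
    "m/s": 1.0,
    "mm/s": 1e-3,
    "cm/s": 1e-2,
    "cm/min": 1e-2 / 60.0,
    "mm/min": 1e-3 / 60.0,
    "m/min": 1.0 / 60.0,
}


def parse_speed(text: str | float) -> float:
    """Parse a rail speed with unit into m/s; bare numbers are m/s.

    >>> parse_speed("344 cm/min")
    0.05733333333333333
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([a-zA-Z/]*)\s*", text)
    if not m:
        raise ValueError(f"cannot parse speed {text!r}")
    value = float(m.group(1))
    unit = m.group(2) or "m/s"
    if unit not in _SPEED_UNITS:
        raise ValueError(f"unknown speed unit {unit!r} (known: {sorted(_SPEED_UNITS)})")
    return value * _SPEED_UNITS[unit]


@dataclass
class RailConfig:
    """Slide-rail motion model.

    speed_a:
        Rail speed, stored in m/s.  Use :meth:`from_speed` to accept
        unit-suffixed input such as ``"344 cm/min"`` (the platform's stock
        setting) or ``"15 mm/s"``.
    fps_f:
        Scanner frame rate (default 15 frames/s).
    travel_axis:
        Axis of rail travel in the sensor frame; ``z`` by default.
    direction:
        +1 or -1 along the travel axis.
    """

    speed_a: float
    fps_f: float = 15.0
    travel_axis: str = "z"
    direction: int = 1

    def __post_init__(self) -> None:
        if self.speed_a <= 0:
            raise ValueError("rail speed must be positive")
        if self.fps_f <= 0:
            raise ValueError("frame rate must be positive")
        if self.travel_axis not in _AXES:
            raise ValueError("travel_axis must be one of x, y, z")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")

    @classmethod
    def from_speed(cls, speed, **kwargs) -> "RailConfig":
        return cls(parse_speed(speed), **kwargs)

    @property
    def step(self) -> float:
        """Sensor displacement between consecutive frames, a/f (m)."""
        return self.speed_a / self.fps_f


def frame_displacement(k: int, rail: RailConfig) -> np.ndarray:
    """Displacement vector d_k of the sensor at frame ``k`` (m).

    Zero except on the travel axis, with magnitude ``k * a / f`` and the
    configured sign.
    """
    if k < 0:
        raise ValueError("frame index must be non-negative")
    d = np.zeros(3)
    d[_AXES[rail.travel_axis]] = rail.direction * k * rail.step
    return d


def stitch(stream: FrameStream, rail: RailConfig) -> PointCloud:
    """Superpose all frames of one acquisition stop into a dense block cloud.

    Every point of frame ``k`` becomes ``P' = P + d_k``; intensity is
    preserved and each output point carries its frame index in
    ``aux["frame"]``.  The output point count equals the sum of the frame
    point counts.
    """
    if not stream.frames:
        raise ValueError("cannot stitch an empty frame stream")
    parts = []
    for f in stream.frames:
        moved = f.points.translated(frame_displacement(f.index, rail))
        moved.aux["frame"] = np.full(len(moved), f.index, dtype=np.int64)
        parts.append(moved)
    return PointCloud.concat(parts, source_tag="stitched")
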