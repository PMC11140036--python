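"""Polarity angle computation on configurable circular axes."""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

from .caves import Cave
from .chunks import Chunk

__all__ = ["AngleConvention", "Measurement", "raw_angle", "convert_axis", "measure_all"]

_COINCIDENT_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class AngleConvention:
    """Circular axis settings for reported angles.

    ``range``: ``unsigned_360`` ([0, 360)) or ``signed_180`` ((-180, 180]).
    ``direction``: ``counterclockwise`` (90 deg = north/up the screen) or
    ``clockwise``. 0 deg always points east (image +x).
    """

    range: str = "unsigned_360"
    direction: str = "counterclockwise"

    def __post_init__(self) -> None:
        if self.range not in ("unsigned_360", "signed_180"):
            raise ValueError("range must be 'unsigned_360' or 'signed_180'")
        if self.direction not in ("counterclockwise", "clockwise"):
            raise ValueError("direction must be 'counterclockwise' or 'clockwise'")


@dataclasses.dataclass(frozen=True)
class Measurement:
    chunk_id: int
    chunk_centroid: tuple[float, float]
    cave_centroid: tuple[float, float]
    angle: float


def raw_angle(
    chunk_centroid: tuple[float, float], cave_centroid: tuple[float, float]
) -> float:
    """Direction of the chunk-to-cave vector, degrees in [0, 360).

    Counterclockwise-positive with 0 = east and 90 = north on screen; the
    y difference is negated because image y grows downward.
    """
    xc, yc = chunk_centroid
    xv, yv = cave_centroid
    if math.hypot(xv - xc, yv - yc) <= _COINCIDENT_TOL:
        raise ValueError("coincident centroids have no defined direction")
    return math.degrees(math.atan2(yc - yv, xv - xc)) % 360.0


def convert_axis(theta: float, conv: AngleConvention) -> float:
    """Map a [0, 360) counterclockwise angle onto the configured axis.

    Direction applies first (clockwise mirrors to ``(360 - theta) % 360``),
    then the range (values > 180 shift by -360 for ``signed_180``).
    """
    a = theta % 360.0
    if conv.direction == "clockwise":
        a = (360.0 - a) % 360.0
    if conv.range == "signed_180" and a > 180.0:
        a -= 360.0
    return a


def measure_all(
    chunks: Sequence[Chunk],
    selected_caves: Mapping[int, Cave | None],
    conv: AngleConvention | None = None,
) -> tuple[list[Measurement], list[Chunk]]:
    """Measure every chunk with a selected cave; collect the rest as bad.

    Chunks with no cave, or whose cave centroid coincides with the chunk
    centroid, get status ``unmeasurable`` and count toward the Bad Count.
    """
    conv = conv or AngleConvention()
    measurements: list[Measurement] = []
    bad: list[Chunk] = []
    for chunk in chunks:
        cave = selected_caves.get(chunk.id)
        if cave is None:
            chunk.status = "unmeasurable"
            bad.append(chunk)
            continue
        cc = chunk.centroid
        vc = cave.centroid
        try:
            theta = raw_angle(cc, vc)
        except ValueError:
            chunk.status = "unmeasurable"
            bad.append(chunk)
            continue
        chunk.status = "processed"
        measurements.append(
            Measurement(
                chunk_id=chunk.id,
                chunk_centroid=cc,
                cave_centroid=vc,
                angle=convert_axis(theta, conv),
            )
        )
    return measurements, bad
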