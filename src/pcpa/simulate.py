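"""Synthetic binary fixtures with known ground-truth polarity.

Shapes mimic the morphologies the pipeline targets: disk-with-hole cells
(labeled surface with an unlabeled circular inclusion), open U/C-shapes
whose mouth faces the true bearing (bundle-like, needing concavity
enclosure), and fused doublet pairs. Rasterization rule: a pixel belongs
to a disk iff its integer center lies inside the continuous disk —
oracles in the test-suite rely on this.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .image_io import BinaryImage

__all__ = [
    "GroundTruthCell",
    "make_disk_cell",
    "make_u_cell",
    "make_doublet",
    "make_tissue",
]

PixelSet = set[tuple[int, int]]


@dataclasses.dataclass(frozen=True)
class GroundTruthCell:
    """Parameters of one synthetic cell.

    ``bearing_deg`` is counterclockwise with 90 = north (up the screen);
    for ``disk_with_hole`` it is the direction from chunk center to the
    hole, for ``u_shape`` the direction the mouth faces.
    """

    center: tuple[float, float]
    radius: float
    cave_offset: float
    bearing_deg: float
    cave_radius: float
    shape: str = "disk_with_hole"


def _disk_pixels(cx: float, cy: float, r: float) -> PixelSet:
    """Pixels whose centers lie within the continuous disk."""
    x0, x1 = math.floor(cx - r), math.ceil(cx + r)
    y0, y1 = math.floor(cy - r), math.ceil(cy + r)
    r2 = r * r
    return {
        (x, y)
        for x in range(x0, x1 + 1)
        for y in range(y0, y1 + 1)
        if (x - cx) ** 2 + (y - cy) ** 2 <= r2
    }


def _bearing_offset(bearing_deg: float, dist: float) -> tuple[float, float]:
    """Screen-coordinate displacement for a counterclockwise bearing."""
    rad = math.radians(bearing_deg)
    return dist * math.cos(rad), -dist * math.sin(rad)


def make_disk_cell(truth: GroundTruthCell) -> tuple[PixelSet, PixelSet]:
    """Rasterize a filled disk with an interior hole along the bearing.

    Returns (chunk_pixels, cave_pixels). The hole must be fully interior:
    ``cave_offset + cave_radius < radius``.
    """
    if truth.cave_offset + truth.cave_radius >= truth.radius:
        raise ValueError("hole must be fully contained inside the disk")
    cx, cy = truth.center
    dx, dy = _bearing_offset(truth.bearing_deg, truth.cave_offset)
    disk = _disk_pixels(cx, cy, truth.radius)
    hole = _disk_pixels(cx + dx, cy + dy, truth.cave_radius)
    return disk - hole, hole & disk


def make_u_cell(truth: GroundTruthCell, mouth_half_angle_deg: float = 40.0) -> PixelSet:
    """Rasterize an open ring (C/U-shape) whose mouth faces the bearing.

    The ring has outer radius ``radius`` and inner radius ``cave_radius``;
    ring pixels within ``mouth_half_angle_deg`` of the bearing are
    removed, leaving an open concavity. Without concavity enclosure the
    cell has no cave; with it, the mouth becomes a single enclosed cave
    whose centroid lies along the bearing.
    """
    cx, cy = truth.center
    outer = _disk_pixels(cx, cy, truth.radius)
    inner_r2 = truth.cave_radius**2
    pixels: PixelSet = set()
    for x, y in outer:
        dx, dy = x - cx, y - cy
        if dx * dx + dy * dy <= inner_r2:
            continue
        ang = math.degrees(math.atan2(-dy, dx))
        diff = abs((ang - truth.bearing_deg + 180.0) % 360.0 - 180.0)
        if diff <= mouth_half_angle_deg:
            continue
        pixels.add((x, y))
    return pixels


def make_doublet(
    truth_a: GroundTruthCell,
    truth_b: GroundTruthCell,
    fusion_axis: str = "horizontal",
) -> tuple[PixelSet, GroundTruthCell, GroundTruthCell]:
    """Fuse two disk-with-hole cells into one connected component.

    ``truth_b`` is repositioned to abut ``truth_a`` along the fusion
    axis (``horizontal`` | ``vertical`` | ``diagonal``); the adjusted
    truths are returned with the union pixel set. Horizontal/vertical
    fusion yields a bounding box with aspect ratio >= 2 for equal radii,
    so doublet splitting recovers both cells.
    """
    ax, ay = truth_a.center
    gap = truth_a.radius + truth_b.radius + 1
    if fusion_axis == "horizontal":
        offset = (gap, 0.0)
    elif fusion_axis == "vertical":
        offset = (0.0, gap)
    elif fusion_axis == "diagonal":
        # Shallow diagonal with slight overlap: the pair stays connected
        # but the straight cut through the bbox midline mixes pixels.
        d = truth_a.radius + truth_b.radius - 1.0
        offset = (d * 2.0 / math.sqrt(5.0), d / math.sqrt(5.0))
    else:
        raise ValueError("fusion_axis must be horizontal, vertical or diagonal")
    truth_b = dataclasses.replace(truth_b, center=(ax + offset[0], ay + offset[1]))
    chunk_a, _ = make_disk_cell(truth_a)
    chunk_b, _ = make_disk_cell(truth_b)
    return chunk_a | chunk_b, truth_a, truth_b


def make_tissue(
    n: int,
    bearing: str | float = "uniform",
    seed: int | None = 0,
    image_size: tuple[int, int] = (1024, 1024),
    radius_range: tuple[float, float] = (19.5, 23.0),
    cave_offset_range: tuple[float, float] = (11.0, 12.5),
    cave_radius: float = 5.0,
    shape: str = "disk_with_hole",
    vonmises_mu: float = 90.0,
    vonmises_kappa: float = 4.0,
    n_speckles: int = 0,
    speckle_size: int = 20,
    max_attempts_per_cell: int = 2000,
) -> tuple[BinaryImage, pd.DataFrame]:
    """Place ``n`` non-overlapping cells with known bearings on a blank image.

    ``bearing`` is ``"uniform"``, ``"vonmises"`` (uses ``vonmises_mu`` /
    ``vonmises_kappa``) or a fixed bearing in degrees. Optional square
    speckles of ``speckle_size`` pixels exercise size exclusion. Output
    is reproducible for a fixed seed. Raises if ``n`` cells cannot be
    placed in the given dimensions.

    Returns the image and a truth table with columns
    ``id, x, y, bearing_deg, shape, radius, cave_offset, cave_radius``.
    """
    rng = np.random.default_rng(seed)
    width, height = image_size
    grid = np.zeros((height, width), dtype=np.uint8)
    margin = radius_range[1] + 14  # keep cells clear of any border-exclusion zone
    if 2 * margin >= min(width, height) and n > 0:
        raise ValueError("image dimensions too small for the requested cells")

    centers: list[tuple[float, float]] = []
    rows = []
    min_sep = 2 * radius_range[1] + 3
    for i in range(n):
        for _ in range(max_attempts_per_cell):
            cx = rng.uniform(margin, width - margin)
            cy = rng.uniform(margin, height - margin)
            if all((cx - ox) ** 2 + (cy - oy) ** 2 >= min_sep**2 for ox, oy in centers):
                break
        else:
            raise ValueError(
                f"could not place cell {i + 1}/{n}; use larger image dimensions"
            )
        centers.append((cx, cy))
        if bearing == "uniform":
            b = float(rng.uniform(0.0, 360.0))
        elif bearing == "vonmises":
            b = float(
                np.degrees(rng.vonmises(np.radians(vonmises_mu), vonmises_kappa))
            ) % 360.0
        else:
            b = float(bearing) % 360.0
        radius = float(rng.uniform(*radius_range))
        # Keep a >= 2 px rim so the rasterized ring cannot develop a
        # diagonal gap that lets the cave leak out.
        offset = min(float(rng.uniform(*cave_offset_range)), radius - cave_radius - 2.0)
        truth = GroundTruthCell(
            center=(cx, cy),
            radius=radius,
            cave_offset=offset,
            bearing_deg=b,
            cave_radius=cave_radius,
            shape=shape,
        )
        if shape == "disk_with_hole":
            chunk, _ = make_disk_cell(truth)
        elif shape == "u_shape":
            chunk = make_u_cell(truth)
        else:
            raise ValueError("shape must be 'disk_with_hole' or 'u_shape'")
        for x, y in chunk:
            grid[y, x] = 1
        rows.append(
            {
                "id": i + 1,
                "x": cx,
                "y": cy,
                "bearing_deg": b,
                "shape": shape,
                "radius": radius,
                "cave_offset": offset,
                "cave_radius": cave_radius,
            }
        )

    placed = 0
    attempts = 0
    side = max(1, int(round(math.sqrt(speckle_size))))
    while placed < n_speckles and attempts < max_attempts_per_cell:
        attempts += 1
        sx = int(rng.uniform(margin, width - margin))
        sy = int(rng.uniform(margin, height - margin))
        if all(
            (sx - ox) ** 2 + (sy - oy) ** 2 >= (min_sep + side) ** 2 for ox, oy in centers
        ):
            grid[sy : sy + side, sx : sx + side] = 1
            centers.append((float(sx), float(sy)))
            placed += 1

    truth_table = pd.DataFrame(
        rows,
        columns=["id", "x", "y", "bearing_deg", "shape", "radius", "cave_offset", "cave_radius"],
    )
    return BinaryImage(grid), truth_table
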