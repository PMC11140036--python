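"""Cave (enclosed background) detection, concavity enclosure and selection.

A cave is a 4-connected aggregate of background pixels fully contained
within a chunk's mass. Open concavities can first be enclosed by adding
one-pixel-thick bridging lines along convex-hull edges ("plastic wrap").
Foreground uses 8-connectivity, background 4-connectivity — the standard
digital-topology pairing that prevents diagonal leaks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import line as draw_line

from .chunks import Chunk
from .image_io import BinaryImage

__all__ = [
    "Cave",
    "CaveSelectionConfig",
    "plastic_wrap",
    "find_caves",
    "filter_caves",
    "select_cave",
    "cave_centroid",
]

_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)

CRITERIA = ("largest", "northmost", "southmost", "eastmost", "westmost")


@dataclasses.dataclass
class Cave:
    """One enclosed background component of a chunk."""

    pixels: set[tuple[int, int]]
    origin: str = "natural"  # "natural" | "wrap_created"

    @property
    def size(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> tuple[float, float]:
        n = len(self.pixels)
        sx = sum(p[0] for p in self.pixels)
        sy = sum(p[1] for p in self.pixels)
        return sx / n, sy / n


@dataclasses.dataclass(frozen=True)
class CaveSelectionConfig:
    min_cave_px: int | None = None
    max_cave_px: int | None = None
    criterion: str = "largest"
    plastic_wrap: bool = True

    def __post_init__(self) -> None:
        if (
            self.min_cave_px is not None
            and self.max_cave_px is not None
            and self.min_cave_px > self.max_cave_px
        ):
            raise ValueError("min_cave_px must not exceed max_cave_px")
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")


def plastic_wrap(chunk: Chunk, image: BinaryImage) -> Chunk:
    """Bridge perimeter concavities with one-pixel-thick lines.

    The convex hull of the chunk's mass pixels is computed and each hull
    edge rasterized as a digital line between its two vertices. An edge
    spans a perimeter break when at least one of its line pixels is
    background *and not 8-adjacent to the chunk* (mere rasterization
    jitter along a digitally convex boundary touches the chunk
    everywhere and is ignored, so wrapping a convex disk is the
    identity). For every such edge, all line pixels not already part of
    the chunk are added to ``wrap_pixels``, keeping the one-pixel bridge
    continuous. Idempotent. Chunks with fewer than 3 non-collinear
    pixels are returned unchanged.
    """
    pts = np.array(sorted(chunk.mass_pixels), dtype=float)
    if len(pts) < 3:
        return chunk
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear pixel set
        return chunk
    verts = pts[hull.vertices].astype(int)
    mask = chunk.mass_pixels

    def touches_mass(p: tuple[int, int]) -> bool:
        x, y = p
        return any(
            (x + dx, y + dy) in mask
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
        )

    for i in range(len(verts)):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % len(verts)]
        rr, cc = draw_line(y0, x0, y1, x1)
        edge = list(zip(cc.tolist(), rr.tolist()))
        gap = [p for p in edge if p not in mask]
        if any(not touches_mass(p) for p in gap):
            chunk.wrap_pixels.update(gap)
    return chunk


def _enclosed_components(
    mass: set[tuple[int, int]],
) -> list[set[tuple[int, int]]]:
    """4-connected background components not reachable from outside the mass.

    Works on the mass bounding box padded by one background pixel; any
    component touching the pad ring is open to the outside.
    """
    xs = [p[0] for p in mass]
    ys = [p[1] for p in mass]
    x0, y0 = min(xs) - 1, min(ys) - 1
    w = max(xs) - x0 + 2
    h = max(ys) - y0 + 2
    grid = np.zeros((h, w), dtype=bool)
    for x, y in mass:
        grid[y - y0, x - x0] = True
    labels, n = ndimage.label(~grid, structure=_FOUR)
    if n == 0:
        return []
    border_labels = set(labels[0, :]) | set(labels[-1, :]) | set(labels[:, 0]) | set(labels[:, -1])
    out: list[set[tuple[int, int]]] = []
    for label in range(1, n + 1):
        if label in border_labels:
            continue
        yy, xx = np.nonzero(labels == label)
        out.append({(int(x) + x0, int(y) + y0) for x, y in zip(xx, yy)})
    # Deterministic order: raster position of each component's first pixel.
    out.sort(key=lambda comp: min((y, x) for x, y in comp))
    return out


def find_caves(chunk: Chunk, image: BinaryImage) -> list[Cave]:
    """Detect the caves of a chunk (wrap pixels act as enclosing boundary).

    A component is ``wrap_created`` when it contains pixels that were not
    enclosed before wrapping (including components merged from natural
    and wrap-opened parts); purely pre-existing components stay
    ``natural``.
    """
    components = _enclosed_components(chunk.mass_pixels)
    if not components:
        return []
    if chunk.wrap_pixels:
        pre = set().union(*_enclosed_components(chunk.pixels)) if chunk.pixels else set()
    else:
        pre = None
    caves = []
    for comp in components:
        if pre is not None and not comp <= pre:
            origin = "wrap_created"
        else:
            origin = "natural"
        caves.append(Cave(pixels=comp, origin=origin))
    return caves


def filter_caves(caves: list[Cave], cfg: CaveSelectionConfig) -> list[Cave]:
    """Drop caves violating the size limits, before selection."""
    out = []
    for cave in caves:
        if cfg.min_cave_px is not None and cave.size < cfg.min_cave_px:
            continue
        if cfg.max_cave_px is not None and cave.size > cfg.max_cave_px:
            continue
        out.append(cave)
    return out


def select_cave(caves: list[Cave], criterion: str = "largest") -> Cave | None:
    """Pick the directional cave of interest, or None if no cave qualifies.

    Ties break by larger size, then smaller centroid y, then smaller
    centroid x, then detection order.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    if not caves:
        return None

    def key(item: tuple[int, Cave]):
        i, cave = item
        cx, cy = cave.centroid
        primary = {
            "largest": -cave.size,
            "northmost": cy,
            "southmost": -cy,
            "eastmost": -cx,
            "westmost": cx,
        }[criterion]
        return (primary, -cave.size, cy, cx, i)

    return min(enumerate(caves), key=key)[1]


def cave_centroid(cave: Cave) -> tuple[float, float]:
    """Arithmetic mean of the cave's pixel coordinates."""
    return cave.centroid
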