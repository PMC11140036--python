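"""Connected-component chunk detection, exclusion filters and doublet splitting."""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
from scipy import ndimage

from .image_io import BinaryImage

__all__ = [
    "Chunk",
    "ChunkFilterConfig",
    "find_chunks",
    "apply_size_filter",
    "apply_border_filter",
    "split_doublets",
    "apply_doublet_split",
]

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)


@dataclasses.dataclass
class Chunk:
    """One 8-connected foreground component.

    ``pixels`` holds ``(x, y)`` coordinates; ``wrap_pixels`` holds bridging
    pixels added by the concavity-enclosing step and counts toward the
    bounding box and centroid ("part of the cell mass").
    """

    id: int
    pixels: set[tuple[int, int]]
    wrap_pixels: set[tuple[int, int]] = dataclasses.field(default_factory=set)
    status: str = "candidate"
    split_origin: str | None = None

    @property
    def size(self) -> int:
        return len(self.pixels)

    @property
    def mass_pixels(self) -> set[tuple[int, int]]:
        """Chunk pixels plus wrap pixels."""
        return self.pixels | self.wrap_pixels

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Tight inclusive bounding box (x_min, y_min, x_max, y_max) of the mass."""
        xs, ys = zip(*self.mass_pixels)
        return min(xs), min(ys), max(xs), max(ys)

    @property
    def centroid(self) -> tuple[float, float]:
        """Mean (x, y) over pixels plus wrap pixels."""
        mass = self.mass_pixels
        n = len(mass)
        sx = sum(p[0] for p in mass)
        sy = sum(p[1] for p in mass)
        return sx / n, sy / n


@dataclasses.dataclass(frozen=True)
class ChunkFilterConfig:
    min_chunk_px: int | None = None
    max_chunk_px: int | None = None
    border_margin_px: int = 0
    doublet_enabled: bool = False
    doublet_ratio: float = 2.0

    def __post_init__(self) -> None:
        if (
            self.min_chunk_px is not None
            and self.max_chunk_px is not None
            and self.min_chunk_px > self.max_chunk_px
        ):
            raise ValueError("min_chunk_px must not exceed max_chunk_px")
        if self.border_margin_px < 0:
            raise ValueError("border_margin_px must be >= 0")
        if self.doublet_ratio <= 1:
            raise ValueError("doublet_ratio must be > 1")


def find_chunks(image: BinaryImage) -> list[Chunk]:
    """Label 8-connected foreground components as chunks.

    Ids start at 1 and follow the raster-scan order of each component's
    first-encountered pixel. An all-background image yields an empty list.
    """
    labels, n = ndimage.label(image.pixels, structure=_EIGHT)
    if n == 0:
        return []
    flat = labels.ravel()
    nonzero = np.flatnonzero(flat)
    # Raster order of first occurrence per label.
    order_values, first_idx = np.unique(flat[nonzero], return_index=True)
    order = order_values[np.argsort(nonzero[first_idx])]
    chunks: list[Chunk] = []
    for new_id, label in enumerate(order, start=1):
        ys, xs = np.nonzero(labels == label)
        chunks.append(Chunk(id=new_id, pixels=set(zip(xs.tolist(), ys.tolist()))))
    return chunks


def apply_size_filter(
    chunks: Iterable[Chunk], cfg: ChunkFilterConfig
) -> tuple[list[Chunk], list[Chunk]]:
    """Split chunks into (kept, size_excluded) by pixel count.

    Only the chunk's own pixels count; wrap pixels are not yet present at
    this stage of the pipeline.
    """
    kept: list[Chunk] = []
    excluded: list[Chunk] = []
    for chunk in chunks:
        too_small = cfg.min_chunk_px is not None and chunk.size < cfg.min_chunk_px
        too_big = cfg.max_chunk_px is not None and chunk.size > cfg.max_chunk_px
        if too_small or too_big:
            chunk.status = "size_excluded"
            excluded.append(chunk)
        else:
            kept.append(chunk)
    return kept, excluded


def apply_border_filter(
    chunks: Iterable[Chunk],
    image_size: tuple[int, int],
    margin: int,
) -> tuple[list[Chunk], list[Chunk]]:
    """Exclude chunks with any pixel within ``margin`` of the image border.

    ``image_size`` is (width, height). A margin of 0 excludes nothing.
    """
    width, height = image_size
    if margin > min(width, height) / 2:
        logger.warning(
            "border margin %d exceeds half the smaller image dimension (%dx%d)",
            margin, width, height,
        )
    kept: list[Chunk] = []
    excluded: list[Chunk] = []
    for chunk in chunks:
        xs = [p[0] for p in chunk.pixels]
        ys = [p[1] for p in chunk.pixels]
        touches = (
            min(xs) < margin
            or min(ys) < margin
            or max(xs) >= width - margin
            or max(ys) >= height - margin
        )
        if touches:
            chunk.status = "border_excluded"
            excluded.append(chunk)
        else:
            kept.append(chunk)
    return kept, excluded


def split_doublets(chunk: Chunk, ratio: float) -> list[Chunk]:
    """Split an elongated chunk in half across its long bounding-box axis.

    With bbox width ``w`` and height ``h`` (inclusive), a chunk is split
    when ``w / h >= ratio`` (vertical cut at ``x_min + w // 2``) or
    ``h / w >= ratio`` (horizontal cut). Pixels strictly below the cut
    coordinate go to the first half, cut-line pixels to the second. The
    two halves partition the parent's pixels and are never re-split. A
    degenerate cut that would leave a half empty returns the chunk
    unchanged.
    """
    if ratio <= 1:
        raise ValueError("ratio must be > 1")
    x0, y0, x1, y1 = chunk.bbox
    w, h = x1 - x0 + 1, y1 - y0 + 1
    if w / h >= ratio:
        cut = x0 + w // 2
        first = {p for p in chunk.pixels if p[0] < cut}
        origins = ("left-half", "right-half")
    elif h / w >= ratio:
        cut = y0 + h // 2
        first = {p for p in chunk.pixels if p[1] < cut}
        origins = ("top-half", "bottom-half")
    else:
        return [chunk]
    second = chunk.pixels - first
    if not first or not second:
        return [chunk]
    return [
        Chunk(id=chunk.id, pixels=first, split_origin=origins[0]),
        Chunk(id=chunk.id, pixels=second, split_origin=origins[1]),
    ]


def apply_doublet_split(chunks: list[Chunk], ratio: float, next_id: int) -> list[Chunk]:
    """Apply :func:`split_doublets` to every chunk, giving halves fresh ids.

    ``next_id`` is the first unused id; split halves are renumbered from
    there so ids stay unique across all chunks of the run.
    """
    out: list[Chunk] = []
    for chunk in chunks:
        halves = split_doublets(chunk, ratio)
        if len(halves) == 2:
            for half in halves:
                half.id = next_id
                next_id += 1
            out.extend(halves)
        else:
            out.append(chunk)
    return out
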