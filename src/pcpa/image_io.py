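"""Reading binary masks and writing annotated / overlay output images.

Images are single-plane 2-D grids. Coordinates follow the screen
convention: ``(x=0, y=0)`` is the top-left pixel, ``x`` grows rightward,
``y`` grows downward. Foreground ("chunk") pixels are 1, background 0.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
from PIL import Image, ImageDraw
from skimage.filters import threshold_otsu

if TYPE_CHECKING:  # pragma: no cover
    from .angles import Measurement
    from .chunks import Chunk

__all__ = [
    "BinaryImage",
    "ColorPalette",
    "UnsupportedImageError",
    "read_mask",
    "write_mask",
    "write_annotated",
    "write_overlay",
]


class UnsupportedImageError(ValueError):
    """Raised for inputs that need upstream preprocessing (RGB, z-stacks)."""


@dataclasses.dataclass(frozen=True)
class BinaryImage:
    """A 2-D binary pixel grid.

    ``pixels`` is a ``(height, width)`` uint8 array with values in {0, 1};
    indexed as ``pixels[y, x]``.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("BinaryImage requires a non-empty 2-D array")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("BinaryImage pixels must be exactly 0 or 1")
        object.__setattr__(self, "pixels", arr.astype(np.uint8, copy=False))

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclasses.dataclass(frozen=True)
class ColorPalette:
    """RGB colors for each annotation category.

    Defaults follow the conventional pseudo-coloring: pink for
    size-excluded, blue for border-excluded, red for unmeasurable,
    yellow for bridging (wrap) pixels, orange text, green arrows.
    Every color is user-overridable.
    """

    size_excluded: tuple[int, int, int] = (255, 105, 180)
    border_excluded: tuple[int, int, int] = (0, 0, 255)
    unmeasurable: tuple[int, int, int] = (255, 0, 0)
    wrap: tuple[int, int, int] = (255, 255, 0)
    text: tuple[int, int, int] = (255, 165, 0)
    arrow: tuple[int, int, int] = (0, 255, 0)


def read_mask(
    path: str | Path,
    threshold: int | str = "auto",
    invert: bool = False,
) -> BinaryImage:
    """Read a grayscale/binary TIFF or PNG and binarize it.

    Images whose values are already a subset of {0, 1} or {0, 255} pass
    through losslessly. Other grayscale images are thresholded: values
    ``>= threshold`` map to 1. ``threshold="auto"`` uses Otsu's method
    (foreground strictly above the Otsu level).

    Parameters
    ----------
    path:
        Single-plane grayscale TIFF or PNG. Multi-channel (RGB/RGBA) or
        z-stack input is rejected.
    threshold:
        Intensity cut in ``[0, 255]`` or ``"auto"``.
    invert:
        Swap foreground and background after binarization, for masks
        drawn with black foreground.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[-1] in (2, 3, 4):
            raise UnsupportedImageError(
                f"{path}: multi-channel image; split channels and convert "
                "to single-plane grayscale before analysis"
            )
        raise UnsupportedImageError(
            f"{path}: z-stack input; project to a single 2-D plane "
            "(e.g. maximum-intensity projection) before analysis"
        )
    if arr.ndim != 2:
        raise UnsupportedImageError(f"{path}: expected a 2-D image, got shape {arr.shape}")

    if arr.dtype == bool:
        binary = arr.astype(np.uint8)
    else:
        values = np.unique(arr)
        if np.isin(values, (0, 1)).all():
            binary = arr.astype(np.uint8)
        elif np.isin(values, (0, 255)).all():
            binary = (arr > 0).astype(np.uint8)
        elif threshold == "auto":
            if values.size == 1:
                # Constant non-binary image: Otsu is undefined; treat as foreground.
                binary = np.ones_like(arr, dtype=np.uint8)
            else:
                binary = (arr > threshold_otsu(arr)).astype(np.uint8)
        else:
            thr = float(threshold)
            binary = (arr >= thr).astype(np.uint8)

    if invert:
        binary = (1 - binary).astype(np.uint8)
    return BinaryImage(binary)


def write_mask(image: BinaryImage, path: str | Path) -> None:
    """Write a BinaryImage as an 8-bit {0, 255} PNG/TIFF (round-trip safe)."""
    iio.imwrite(path, (image.pixels * np.uint8(255)))


def _draw_arrow(
    draw: ImageDraw.ImageDraw,
    start: tuple[float, float],
    angle_ccw_deg: float,
    length: float,
    color: tuple[int, int, int] | tuple[int, int, int, int],
) -> None:
    """Draw an arrow from ``start`` along a counterclockwise screen angle.

    0 deg points east; 90 deg points up the screen (decreasing y).
    """
    rad = math.radians(angle_ccw_deg)
    dx, dy = math.cos(rad), -math.sin(rad)
    x0, y0 = start
    x1, y1 = x0 + dx * length, y0 + dy * length
    draw.line([(x0, y0), (x1, y1)], fill=color, width=1)
    # Two arrowhead barbs at +/- 150 deg from the shaft direction.
    head = max(2.0, length * 0.25)
    for side in (150.0, -150.0):
        barb = math.radians(angle_ccw_deg + side)
        bx, by = math.cos(barb), -math.sin(barb)
        draw.line([(x1, y1), (x1 + bx * head, y1 + by * head)], fill=color, width=1)


def _measurement_direction(m: "Measurement") -> float:
    """Screen angle (ccw deg, 0 = east) of the chunk-to-cave vector."""
    (xc, yc), (xv, yv) = m.chunk_centroid, m.cave_centroid
    return math.degrees(math.atan2(yc - yv, xv - xc)) % 360.0


def write_annotated(
    image: BinaryImage,
    results: Sequence["Measurement"],
    categorized: Mapping[str, Sequence["Chunk"]],
    palette: ColorPalette | None = None,
    path: str | Path | None = None,
) -> np.ndarray:
    """Write the annotated RGB output image.

    Processed chunks stay white and receive an id number, the angle text
    and a directional arrow; excluded chunks are pseudo-colored by
    category; bridging (wrap) pixels are shown in ``palette.wrap``.

    ``categorized`` maps ``processed`` / ``size_excluded`` /
    ``border_excluded`` / ``unmeasurable`` to the corresponding chunk
    lists. Returns the rendered array (and writes it when ``path`` given).
    """
    palette = palette or ColorPalette()
    h, w = image.pixels.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[image.pixels == 1] = (255, 255, 255)

    category_colors = {
        "size_excluded": palette.size_excluded,
        "border_excluded": palette.border_excluded,
        "unmeasurable": palette.unmeasurable,
    }
    for category, color in category_colors.items():
        for chunk in categorized.get(category, ()):  # type: ignore[union-attr]
            for x, y in chunk.pixels:
                rgb[y, x] = color

    by_id = {}
    for chunk in categorized.get("processed", ()):
        by_id[chunk.id] = chunk
        for x, y in chunk.wrap_pixels:
            rgb[y, x] = palette.wrap
    # Unmeasurable chunks may also carry wrap pixels worth showing.
    for chunk in categorized.get("unmeasurable", ()):
        for x, y in chunk.wrap_pixels:
            rgb[y, x] = palette.wrap

    pil = Image.fromarray(rgb)
    draw = ImageDraw.Draw(pil)
    draw.fontmode = "1"  # aliased text keeps exact palette colors
    for m in results:
        chunk = by_id.get(m.chunk_id)
        if chunk is not None:
            x0, y0, x1, y1 = chunk.bbox
            length = 0.8 * math.hypot(x1 - x0 + 1, y1 - y0 + 1)
        else:
            length = max(8.0, 2.0 * math.dist(m.chunk_centroid, m.cave_centroid))
        _draw_arrow(draw, m.chunk_centroid, _measurement_direction(m), length, palette.arrow)
    for m in results:
        cx, cy = m.chunk_centroid
        draw.text((cx + 2, cy + 2), f"{m.chunk_id}", fill=palette.text)
        draw.text((cx + 2, cy + 12), f"{m.angle:.1f}", fill=palette.text)

    out = np.asarray(pil)
    if path is not None:
        iio.imwrite(path, out)
    return out


def write_overlay(
    results: Sequence["Measurement"],
    width: int,
    height: int,
    palette: ColorPalette | None = None,
    path: str | Path | None = None,
) -> np.ndarray:
    """Write the RGBA overlay (transparent background) with ids, angles, arrows.

    The background alpha is 0 so the overlay composites over the original
    micrograph with zero-transparent semantics.
    """
    palette = palette or ColorPalette()
    pil = Image.new("RGBA", (width, height), (0, 0, 0, 0))
    draw = ImageDraw.Draw(pil)
    draw.fontmode = "1"
    arrow_rgba = (*palette.arrow, 255)
    text_rgba = (*palette.text, 255)
    for m in results:
        length = max(8.0, 2.0 * math.dist(m.chunk_centroid, m.cave_centroid))
        _draw_arrow(draw, m.chunk_centroid, _measurement_direction(m), length, arrow_rgba)
    for m in results:
        cx, cy = m.chunk_centroid
        draw.text((cx + 2, cy + 2), f"{m.chunk_id}", fill=text_rgba)
        draw.text((cx + 2, cy + 12), f"{m.angle:.1f}", fill=text_rgba)
    out = np.asarray(pil)
    if path is not None:
        iio.imwrite(path, out)
    return out
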