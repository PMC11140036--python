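from __future__ import annotations

import numpy as np
import pytest

from pcpa import BinaryImage, Chunk


def image_from_pixels(
    pixels: set[tuple[int, int]], width: int | None = None, height: int | None = None
) -> BinaryImage:
    """Build a BinaryImage with the given (x, y) pixels set to 1."""
    if pixels:
        w = (width or max(p[0] for p in pixels) + 3)
        h = (height or max(p[1] for p in pixels) + 3)
    else:
        w, h = width or 8, height or 8
    arr = np.zeros((h, w), dtype=np.uint8)
    for x, y in pixels:
        arr[y, x] = 1
    return BinaryImage(arr)


def chunk_from_pixels(pixels: set[tuple[int, int]], chunk_id: int = 1) -> Chunk:
    return Chunk(id=chunk_id, pixels=set(pixels))


def rect(x0: int, y0: int, w: int, h: int) -> set[tuple[int, int]]:
    return {(x, y) for x in range(x0, x0 + w) for y in range(y0, y0 + h)}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
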