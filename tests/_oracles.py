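"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy/skimage so they share no code path with
the package: labeling by BFS flood fill, enclosure by border flood fill,
circular statistics by direct per-angle trigonometric summation.
"""

from __future__ import annotations

import cmath
import math
from collections import deque

import numpy as np


def flood_fill_label(arr: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected labeling of nonzero pixels, pure-python BFS.

    Labels start at 1 in raster-scan order of each component's first pixel.
    """
    h, w = arr.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for y in range(h):
        for x in range(w):
            if arr[y, x] and labels[y, x] == 0:
                current += 1
                queue = deque([(x, y)])
                labels[y, x] = current
                while queue:
                    qx, qy = queue.popleft()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            nx, ny = qx + dx, qy + dy
                            if 0 <= nx < w and 0 <= ny < h:
                                if arr[ny, nx] and labels[ny, nx] == 0:
                                    labels[ny, nx] = current
                                    queue.append((nx, ny))
    return labels, current


def enclosed_background(mass: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Background pixels unreachable (4-connected) from outside the mass.

    Flood-fills background from a padded frame around the mass bounding
    box; whatever background remains is enclosed.
    """
    xs = [p[0] for p in mass]
    ys = [p[1] for p in mass]
    x0, x1 = min(xs) - 1, max(xs) + 1
    y0, y1 = min(ys) - 1, max(ys) + 1
    outside: set[tuple[int, int]] = set()
    queue = deque([(x0, y0)])
    outside.add((x0, y0))
    while queue:
        x, y = queue.popleft()
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nx, ny = x + dx, y + dy
            if x0 <= nx <= x1 and y0 <= ny <= y1:
                p = (nx, ny)
                if p not in mass and p not in outside:
                    outside.add(p)
                    queue.append(p)
    return {
        (x, y)
        for x in range(x0, x1 + 1)
        for y in range(y0, y1 + 1)
        if (x, y) not in mass and (x, y) not in outside
    }


def circular_stats_reference(angles_deg: list[float]) -> tuple[float, float, float, float]:
    """(mean_deg in [0,360), rml, variance, sd_deg) by direct summation."""
    n = len(angles_deg)
    total = sum(cmath.exp(1j * math.radians(a)) for a in angles_deg)
    rml = abs(total) / n
    if rml < 1e-12:
        return float("nan"), 0.0, 1.0, float("inf")
    mean = math.degrees(cmath.phase(total)) % 360.0
    sd = math.degrees(math.sqrt(-2.0 * math.log(min(rml, 1.0)))) if rml < 1.0 else 0.0
    return mean, rml, 1.0 - rml, sd


def circular_error(a: float, b: float) -> float:
    """Smallest absolute angular difference in degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)
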