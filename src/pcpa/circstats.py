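"""Fisher circular descriptive statistics and rose diagrams.

Given angles theta_i (degrees, treated on whatever axis they were
measured): C = sum cos(theta_i), S = sum sin(theta_i), R = sqrt(C^2 + S^2).
The mean direction is atan2(S, C), the resultant mean length (RML) is
R / n, the circular variance 1 - RML, and the circular standard
deviation sqrt(-2 ln RML), reported in degrees.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .angles import AngleConvention

if TYPE_CHECKING:  # pragma: no cover
    from .angles import Measurement
    from .chunks import Chunk

__all__ = ["SummaryStats", "circular_summary", "summarize", "rose_diagram"]

logger = logging.getLogger(__name__)

_RML_ZERO_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class SummaryStats:
    processed_count: int
    bad_count: int
    total_count: int
    processed_pct: float
    mean_angle: float  # degrees on the configured axis; NaN when undefined
    rml: float
    circ_variance: float  # unitless, 1 - rml
    circ_sd: float  # degrees


def _range_map(mean_deg: float, conv: AngleConvention) -> float:
    """Map a mean direction onto the convention's numeric range.

    The input angles are already on the user's axis, so only the range
    (not the direction) needs remapping here.
    """
    a = mean_deg % 360.0
    if conv.range == "signed_180" and a > 180.0:
        a -= 360.0
    return a


def circular_summary(
    angles: Sequence[float], conv: AngleConvention | None = None
) -> tuple[float, float, float, float]:
    """Return (mean_angle, rml, circ_variance, circ_sd) for angles in degrees.

    When the resultant length vanishes (fully dispersed data) the mean is
    undefined: NaN is returned with an infinite circular SD and a logged
    warning.
    """
    if len(angles) == 0:
        raise ValueError("circular_summary requires at least one angle")
    conv = conv or AngleConvention()
    rad = np.radians(np.asarray(angles, dtype=float))
    c = float(np.sum(np.cos(rad)))
    s = float(np.sum(np.sin(rad)))
    r = math.hypot(c, s)
    rml = r / len(angles)
    if rml <= _RML_ZERO_TOL:
        logger.warning("resultant mean length is 0; mean angle undefined")
        return float("nan"), 0.0, 1.0, float("inf")
    mean = _range_map(math.degrees(math.atan2(s, c)), conv)
    variance = 1.0 - rml
    sd = math.degrees(math.sqrt(-2.0 * math.log(rml))) if rml < 1.0 else 0.0
    return mean, min(rml, 1.0), variance, sd


def summarize(
    measurements: Sequence["Measurement"],
    bad_chunks: Sequence["Chunk"],
    conv: AngleConvention | None = None,
) -> SummaryStats:
    """Build the run summary: counts plus circular statistics of the angles."""
    processed = len(measurements)
    bad = len(bad_chunks)
    total = processed + bad
    pct = 100.0 * processed / total if total else 0.0
    if processed:
        mean, rml, variance, sd = circular_summary([m.angle for m in measurements], conv)
    else:
        mean = rml = variance = sd = float("nan")
    return SummaryStats(
        processed_count=processed,
        bad_count=bad,
        total_count=total,
        processed_pct=pct,
        mean_angle=mean,
        rml=rml,
        circ_variance=variance,
        circ_sd=sd,
    )


def rose_diagram(
    angles: Sequence[float],
    bin_width: float = 15.0,
    path: str | Path | None = None,
) -> tuple[np.ndarray, Path | None]:
    """Bin angles into half-open [k*w, (k+1)*w) wedges and plot a rose diagram.

    ``bin_width`` must divide 360 evenly. The mean direction is drawn as
    a radial black line (omitted for empty or fully dispersed data).
    Returns the bin counts and the written path. Usable stand-alone on
    any numeric angle list.
    """
    n_exact = 360.0 / bin_width if bin_width > 0 else float("nan")
    if not (bin_width > 0 and math.isclose(n_exact, round(n_exact), abs_tol=1e-9)):
        raise ValueError("bin_width must evenly divide 360")
    n_bins = round(n_exact)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    wrapped = np.asarray(angles, dtype=float) % 360.0
    counts, _ = np.histogram(wrapped, bins=edges)

    if path is not None:
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
        centers = np.radians(edges[:-1] + bin_width / 2.0)
        ax.bar(
            centers,
            counts,
            width=np.radians(bin_width),
            bottom=0.0,
            color="#4878a8",
            edgecolor="black",
            linewidth=0.5,
        )
        if len(wrapped):
            mean, rml, _, _ = circular_summary(wrapped.tolist())
            if not math.isnan(mean):
                rmax = counts.max() if counts.max() > 0 else 1
                ax.plot([0, math.radians(mean)], [0, rmax], color="black", linewidth=2)
        ax.set_theta_zero_location("E")
        ax.set_theta_direction(1)
        fig.savefig(path, dpi=150)
        plt.close(fig)
        path = Path(path)
    return counts, path
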