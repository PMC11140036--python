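"""Single-image and batch orchestration, and tabular/graphical outputs.

Stage order: read -> find chunks -> size filter -> doublet split ->
border filter -> concavity enclosure -> centroids -> cave
detection/filtering/selection -> angle measurement -> summary.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .angles import Measurement, measure_all
from .caves import filter_caves, find_caves, plastic_wrap, select_cave
from .chunks import (
    Chunk,
    apply_border_filter,
    apply_doublet_split,
    apply_size_filter,
    find_chunks,
)
from .circstats import SummaryStats, rose_diagram, summarize
from .config import RunConfig
from .image_io import BinaryImage, read_mask, write_annotated, write_overlay

__all__ = ["AnalysisResult", "analyze_image", "run_single", "run_batch", "BatchError"]

logger = logging.getLogger(__name__)

RESULTS_COLUMNS = ["chunk_id", "chunk_x", "chunk_y", "angle_deg"]
SUMMARY_COLUMNS = [
    "processed_count",
    "bad_count",
    "total_count",
    "processed_pct",
    "mean_angle_deg",
    "rml",
    "circ_variance",
    "circ_sd_deg",
]


class BatchError(RuntimeError):
    """Raised when a batch run finishes but some images could not be read."""


@dataclasses.dataclass
class AnalysisResult:
    measurements: list[Measurement]
    summary: SummaryStats
    categorized: dict[str, list[Chunk]]
    image: BinaryImage

    @property
    def results_table(self) -> pd.DataFrame:
        rows = [
            {
                "chunk_id": m.chunk_id,
                "chunk_x": m.chunk_centroid[0],
                "chunk_y": m.chunk_centroid[1],
                "angle_deg": m.angle,
            }
            for m in sorted(self.measurements, key=lambda m: m.chunk_id)
        ]
        return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


def analyze_image(image: BinaryImage, cfg: RunConfig | None = None) -> AnalysisResult:
    """Run the full measurement pipeline on an in-memory binary image."""
    cfg = cfg or RunConfig()
    chunks = find_chunks(image)
    max_id = max((c.id for c in chunks), default=0)

    kept, size_excluded = apply_size_filter(chunks, cfg.chunk_cfg)
    if cfg.doublet_enabled:
        kept = apply_doublet_split(kept, cfg.doublet_ratio, next_id=max_id + 1)
    kept, border_excluded = apply_border_filter(
        kept, (image.width, image.height), cfg.border_margin_px
    )
    if cfg.plastic_wrap:
        for chunk in kept:
            plastic_wrap(chunk, image)

    selected = {}
    for chunk in kept:
        caves = filter_caves(find_caves(chunk, image), cfg.cave_cfg)
        selected[chunk.id] = select_cave(caves, cfg.cave_criterion)
    measurements, bad = measure_all(kept, selected, cfg.convention)
    summary = summarize(measurements, bad, cfg.convention)

    processed = [c for c in kept if c.status == "processed"]
    logger.info(
        "chunks: %d processed, %d unmeasurable, %d size-excluded, %d border-excluded",
        len(processed), len(bad), len(size_excluded), len(border_excluded),
    )
    return AnalysisResult(
        measurements=measurements,
        summary=summary,
        categorized={
            "processed": processed,
            "unmeasurable": bad,
            "size_excluded": size_excluded,
            "border_excluded": border_excluded,
        },
        image=image,
    )


def _format_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fix float formatting (3 decimals) so CSV output is byte-stable."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: f"{v:.3f}" if math.isfinite(v) else str(v))
    return out


def summary_to_frame(summary: SummaryStats) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "processed_count": summary.processed_count,
                "bad_count": summary.bad_count,
                "total_count": summary.total_count,
                "processed_pct": summary.processed_pct,
                "mean_angle_deg": summary.mean_angle,
                "rml": summary.rml,
                "circ_variance": summary.circ_variance,
                "circ_sd_deg": summary.circ_sd,
            }
        ],
        columns=SUMMARY_COLUMNS,
    )


def _write_artifacts(
    result: AnalysisResult,
    results_table: pd.DataFrame,
    cfg: RunConfig,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg.outputs.results:
        _format_table(results_table).to_csv(out_dir / "results.csv", index=False)
    if cfg.outputs.summary:
        _format_table(summary_to_frame(result.summary)).to_csv(
            out_dir / "summary.csv", index=False
        )
    if cfg.outputs.rose:
        rose_diagram(
            [m.angle for m in result.measurements],
            bin_width=cfg.rose_bin_width,
            path=out_dir / "rose.png",
        )
    if cfg.outputs.annotated:
        write_annotated(
            result.image,
            result.measurements,
            result.categorized,
            cfg.palette,
            out_dir / "annotated.png",
        )
    if cfg.outputs.overlay:
        write_overlay(
            result.measurements,
            result.image.width,
            result.image.height,
            cfg.palette,
            out_dir / "overlay.png",
        )
    cfg.save(out_dir / "effective-config.json")


def run_single(
    image_path: str | Path, cfg: RunConfig | None = None, out_dir: str | Path | None = None
) -> AnalysisResult:
    """Analyze one image and (optionally) write the enabled artifacts."""
    cfg = cfg or RunConfig()
    image = read_mask(image_path, threshold=cfg.threshold, invert=cfg.invert)
    result = analyze_image(image, cfg)
    if out_dir is not None:
        _write_artifacts(result, result.results_table, cfg, Path(out_dir))
    return result


def run_batch(
    image_paths: Sequence[str | Path],
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, SummaryStats, list[Path]]:
    """Analyze several images and pool the per-cell rows into one data set.

    The pooled results table carries a ``source`` column; the pooled
    summary and rose diagram are computed over the concatenated raw
    angles (never over per-image means). Unreadable images are logged
    and skipped; if any were skipped a :class:`BatchError` is raised
    after the remaining work completes.
    """
    if not image_paths:
        raise ValueError("run_batch requires at least one image path")
    cfg = cfg or RunConfig()
    pooled_frames: list[pd.DataFrame] = []
    all_measurements: list[Measurement] = []
    all_bad: list[Chunk] = []
    per_image_summaries: list[pd.DataFrame] = []
    failed: list[Path] = []

    for path in image_paths:
        path = Path(path)
        try:
            image = read_mask(path, threshold=cfg.threshold, invert=cfg.invert)
        except Exception as exc:  # noqa: BLE001 - any unreadable input is skipped
            logger.error("skipping %s: %s", path, exc)
            failed.append(path)
            continue
        result = analyze_image(image, cfg)
        table = result.results_table
        table.insert(0, "source", path.name)
        pooled_frames.append(table)
        all_measurements.extend(result.measurements)
        all_bad.extend(result.categorized["unmeasurable"])
        per_summary = summary_to_frame(result.summary)
        per_summary.insert(0, "source", path.name)
        per_image_summaries.append(per_summary)

    pooled = (
        pd.concat(pooled_frames, ignore_index=True)
        if pooled_frames
        else pd.DataFrame(columns=["source", *RESULTS_COLUMNS])
    )
    pooled_summary = summarize(all_measurements, all_bad, cfg.convention)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if cfg.outputs.results:
            _format_table(pooled).to_csv(out / "results.csv", index=False)
        if cfg.outputs.summary:
            _format_table(summary_to_frame(pooled_summary)).to_csv(
                out / "summary.csv", index=False
            )
            if per_image_summaries:
                _format_table(pd.concat(per_image_summaries, ignore_index=True)).to_csv(
                    out / "summary_per_image.csv", index=False
                )
        if cfg.outputs.rose:
            rose_diagram(
                [m.angle for m in all_measurements],
                bin_width=cfg.rose_bin_width,
                path=out / "rose.png",
            )
        cfg.save(out / "effective-config.json")

    if failed:
        raise BatchError(
            f"{len(failed)} of {len(image_paths)} images could not be read: "
            + ", ".join(str(p) for p in failed)
        )
    return pooled, pooled_summary, failed
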