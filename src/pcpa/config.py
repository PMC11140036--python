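"""Run configuration: defaults, file loading, flag overrides, validation."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

from .angles import AngleConvention
from .caves import CRITERIA, CaveSelectionConfig
from .chunks import ChunkFilterConfig
from .image_io import ColorPalette

__all__ = ["OutputToggles", "RunConfig", "load_config", "DEFAULT_CONFIG"]


@dataclasses.dataclass(frozen=True)
class OutputToggles:
    results: bool = True
    summary: bool = True
    rose: bool = True
    annotated: bool = True
    overlay: bool = True


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Effective settings for one analysis run.

    Defaults reproduce a typical cochlear configuration: noise removal
    at 500 px, 10 px border exclusion, concavity enclosure on, doublet
    ratio 2.0, caves under 15 px ignored, largest cave selected, angles
    on a counterclockwise 0-360 axis.
    """

    min_chunk_px: int | None = 500
    max_chunk_px: int | None = None
    border_margin_px: int = 10
    doublet_enabled: bool = True
    doublet_ratio: float = 2.0
    plastic_wrap: bool = True
    min_cave_px: int | None = 15
    max_cave_px: int | None = None
    cave_criterion: str = "largest"
    angle_range: str = "unsigned_360"
    angle_direction: str = "counterclockwise"
    rose_bin_width: float = 15.0
    threshold: int | str = "auto"
    invert: bool = False
    seed: int | None = None
    outputs: OutputToggles = dataclasses.field(default_factory=OutputToggles)
    palette: ColorPalette = dataclasses.field(default_factory=ColorPalette)

    @property
    def chunk_cfg(self) -> ChunkFilterConfig:
        return ChunkFilterConfig(
            min_chunk_px=self.min_chunk_px,
            max_chunk_px=self.max_chunk_px,
            border_margin_px=self.border_margin_px,
            doublet_enabled=self.doublet_enabled,
            doublet_ratio=self.doublet_ratio,
        )

    @property
    def cave_cfg(self) -> CaveSelectionConfig:
        return CaveSelectionConfig(
            min_cave_px=self.min_cave_px,
            max_cave_px=self.max_cave_px,
            criterion=self.cave_criterion,
            plastic_wrap=self.plastic_wrap,
        )

    @property
    def convention(self) -> AngleConvention:
        return AngleConvention(range=self.angle_range, direction=self.angle_direction)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["palette"] = {k: list(v) for k, v in dataclasses.asdict(self.palette).items()}
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


DEFAULT_CONFIG = RunConfig()

_SCALAR_KEYS = {
    f.name for f in dataclasses.fields(RunConfig) if f.name not in ("outputs", "palette")
}


def _validate(cfg: RunConfig) -> list[str]:
    errors = []
    if cfg.min_chunk_px is not None and cfg.min_chunk_px < 0:
        errors.append("min_chunk_px must be >= 0")
    if (
        cfg.min_chunk_px is not None
        and cfg.max_chunk_px is not None
        and cfg.min_chunk_px > cfg.max_chunk_px
    ):
        errors.append("min_chunk_px must not exceed max_chunk_px")
    if cfg.border_margin_px < 0:
        errors.append("border_margin_px must be >= 0")
    if cfg.doublet_ratio <= 1:
        errors.append("doublet_ratio must be > 1")
    if (
        cfg.min_cave_px is not None
        and cfg.max_cave_px is not None
        and cfg.min_cave_px > cfg.max_cave_px
    ):
        errors.append("min_cave_px must not exceed max_cave_px")
    if cfg.cave_criterion not in CRITERIA:
        errors.append(f"cave_criterion must be one of {CRITERIA}")
    if cfg.angle_range not in ("unsigned_360", "signed_180"):
        errors.append("angle_range must be 'unsigned_360' or 'signed_180'")
    if cfg.angle_direction not in ("counterclockwise", "clockwise"):
        errors.append("angle_direction must be 'counterclockwise' or 'clockwise'")
    if cfg.rose_bin_width <= 0 or round(360.0 / cfg.rose_bin_width) * cfg.rose_bin_width != 360.0:
        errors.append("rose_bin_width must evenly divide 360")
    if cfg.threshold != "auto":
        try:
            t = float(cfg.threshold)
        except (TypeError, ValueError):
            errors.append("threshold must be 'auto' or a number in [0, 255]")
        else:
            if not 0 <= t <= 255:
                errors.append("threshold must be 'auto' or a number in [0, 255]")
    return errors


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Build the effective RunConfig.

    Precedence: CLI/keyword overrides > config-file values > defaults.
    Unknown keys or out-of-range values raise ``ValueError`` listing every
    offending field.
    """
    data: dict[str, Any] = {}
    if path is not None:
        data.update(json.loads(Path(path).read_text()))
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = sorted(set(data) - _SCALAR_KEYS - {"outputs", "palette"})
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")

    kwargs: dict[str, Any] = {k: v for k, v in data.items() if k in _SCALAR_KEYS}
    if "outputs" in data:
        toggles = data["outputs"]
        bad = sorted(set(toggles) - {f.name for f in dataclasses.fields(OutputToggles)})
        if bad:
            raise ValueError(f"unknown output toggles: {', '.join(bad)}")
        kwargs["outputs"] = OutputToggles(**toggles)
    if "palette" in data:
        colors = data["palette"]
        bad = sorted(set(colors) - {f.name for f in dataclasses.fields(ColorPalette)})
        if bad:
            raise ValueError(f"unknown palette entries: {', '.join(bad)}")
        kwargs["palette"] = ColorPalette(**{k: tuple(v) for k, v in colors.items()})

    cfg = RunConfig(**kwargs)
    errors = _validate(cfg)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cfg
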