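"""Run configuration: YAML parsing and validation for batch processing."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .dyes import BUILTIN_DYES, DyeSpec
from .io import Channel
from .roi import CircularROI

__all__ = ["ConfigError", "RoiConfig", "WellEntry", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Raised on an unparsable or inconsistent run configuration; the
    message names the offending field path."""


@dataclass(frozen=True)
class RoiConfig:
    """Exactly one ROI mode: a manual circle, automatic well detection, or
    spheroid-body segmentation.  A manual circle always overrides detection."""

    mode: str  # "circle" | "detect" | "spheroid" | "full_image"
    circle: CircularROI | None = None
    expected_radius_px: float | None = None
    tolerance_fraction: float = 0.2


@dataclass(frozen=True)
class WellEntry:
    """One well's channel-file triple plus its metadata."""

    well_id: str
    red_path: Path
    green_path: Path
    blue_path: Path
    cell_line: str = ""
    lineage: str = ""
    condition: str = "differentiated"
    timepoint_days: float = float("nan")
    dye: str = "alizarin_red_s"


@dataclass(frozen=True)
class RunConfig:
    """Validated batch-run configuration."""

    wells: tuple[WellEntry, ...]
    roi: RoiConfig
    pixel_size_um: float = 1.0
    dyes: dict[str, DyeSpec] = field(default_factory=dict)
    output_dir: Path = Path("results")
    value_column: str = "positive_count"  # measurement entering the ranking
    write_masks: bool = False
    seed: int = 0

    def dye_for(self, name: str) -> DyeSpec:
        key = name.lower().replace(" ", "_")
        if key in self.dyes:
            return self.dyes[key]
        if key in BUILTIN_DYES:
            return BUILTIN_DYES[key]
        raise ConfigError(f"wells[*].dye: unknown dye {name!r}")


def _parse_dye(name: str, block: dict[str, Any]) -> DyeSpec:
    try:
        return DyeSpec(
            name=block.get("name", name),
            signal_channels=frozenset(Channel(c) for c in block["signal_channels"]),
            complement_channels=frozenset(Channel(c) for c in block["complement_channels"]),
            threshold=float(block["threshold"]),
        )
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"dyes.{name}: {exc}") from exc


def _parse_roi(block: dict[str, Any]) -> RoiConfig:
    if not isinstance(block, dict) or len(block) != 1:
        raise ConfigError("roi: exactly one of circle/detect/spheroid/full_image is required")
    mode, body = next(iter(block.items()))
    if mode == "circle":
        try:
            circle = CircularROI(float(body["cx"]), float(body["cy"]), float(body["r"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"roi.circle: needs cx, cy, r ({exc})") from exc
        return RoiConfig(mode="circle", circle=circle)
    if mode == "detect":
        try:
            return RoiConfig(
                mode="detect",
                expected_radius_px=float(body["expected_radius_px"]),
                tolerance_fraction=float(body.get("tolerance_fraction", 0.2)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"roi.detect: needs expected_radius_px ({exc})") from exc
    if mode in ("spheroid", "full_image"):
        return RoiConfig(mode=mode)
    raise ConfigError(f"roi.{mode}: unknown ROI mode")


def load_config(path: Path | str) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    base = path.parent

    dyes = {
        name: _parse_dye(name, block) for name, block in (raw.get("dyes") or {}).items()
    }

    wells_raw = raw.get("wells")
    if not wells_raw:
        raise ConfigError("wells: at least one well entry is required")
    wells = []
    for i, w in enumerate(wells_raw):
        try:
            wells.append(
                WellEntry(
                    well_id=str(w["well_id"]),
                    red_path=base / w["red"],
                    green_path=base / w["green"],
                    blue_path=base / w["blue"],
                    cell_line=str(w.get("cell_line", "")),
                    lineage=str(w.get("lineage", "")),
                    condition=str(w.get("condition", "differentiated")),
                    timepoint_days=float(w.get("timepoint_days", "nan")),
                    dye=str(w.get("dye", "alizarin_red_s")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"wells[{i}]: {exc}") from exc

    config = RunConfig(
        wells=tuple(wells),
        roi=_parse_roi(raw.get("roi", {"full_image": {}})),
        pixel_size_um=float(raw.get("pixel_size_um", 1.0)),
        dyes=dyes,
        output_dir=base / raw.get("output_dir", "results"),
        value_column=str(raw.get("value_column", "positive_count")),
        write_masks=bool(raw.get("write_masks", False)),
        seed=int(raw.get("seed", 0)),
    )
    for i, w in enumerate(config.wells):
        try:
            config.dye_for(w.dye)
        except ConfigError as exc:
            raise ConfigError(f"wells[{i}].dye: unknown dye {w.dye!r}") from exc
    return config
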