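"""Synthetic well scans, tile grids, spheroid sections and time courses
with exact ground truth.

The generator emulates the geometry of a stained whole-well bright-field
scan: a bright circular well bottom on a darker plate background, stained
regions whose signal channels dominate (or are dominated by) their
complements at a chosen target ratio, dirt blobs of arbitrary hue, and
additive Gaussian pixel noise applied after ground-truth derivation.

Ground truth is derived from the noiseless integer image by a plain
per-pixel Python loop that re-implements the ratio rule independently of
:mod:`stainquant.dyes`, so the two implementations cross-validate each
other in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Channel, ChannelPlane, ColorComposite, TileGridSpec, composite_from_arrays
from .roi import CircularROI

__all__ = [
    "StainSpot",
    "DirtBlob",
    "SyntheticWellSpec",
    "GroundTruth",
    "generate_well",
    "generate_tiles",
    "generate_spheroid_section",
    "generate_time_course",
]

# independent copy of the built-in dye definitions used only for truth
# derivation; deliberately NOT imported from stainquant.dyes
_TRUTH_DYES: dict[str, tuple[tuple[str, ...], tuple[str, ...], float]] = {
    "alizarin_red_s": (("red",), ("green", "blue"), 1.0),
    "oil_red_o": (("red",), ("green", "blue"), 1.0),
    "alcian_blue_8gx": (("green", "blue"), ("red",), 4.0),
}


@dataclass(frozen=True)
class StainSpot:
    """A flat-top stained disc with optional linear edge falloff.

    ``ratio`` is the target signal/complement ratio at full stain; inside
    the falloff band the stain mixes linearly into the neutral well
    background, so edge pixels may straddle the positivity threshold and
    are assigned by the noiseless ratio rule (truth stays exact).
    """

    center_x: float
    center_y: float
    radius: float
    dye_name: str = "alizarin_red_s"
    ratio: float = 3.0
    edge_falloff_px: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("spot radius must be positive")
        if self.dye_name not in _TRUTH_DYES:
            raise ValueError(f"unknown dye {self.dye_name!r}")
        if self.ratio <= 0:
            raise ValueError("target ratio must be positive")
        if not 0 <= self.edge_falloff_px <= self.radius:
            raise ValueError("edge falloff must lie in [0, radius]")


@dataclass(frozen=True)
class DirtBlob:
    """A debris disc that scales all channels by a per-channel hue factor.

    A neutral hue (equal factors) darkens the pixel without changing any
    channel ratio, so neutral dirt can never become dye-positive.
    """

    center_x: float
    center_y: float
    radius: float
    hue: tuple[float, float, float] = (0.3, 0.3, 0.3)  # (red, green, blue) factors

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("blob radius must be positive")
        if any(not 0 < h <= 1 for h in self.hue):
            raise ValueError("hue factors must lie in (0, 1]")


@dataclass(frozen=True)
class SyntheticWellSpec:
    """Full description of one synthetic well scan; (spec, seed) fixes the output."""

    image_size_px: tuple[int, int] = (512, 512)  # (height, width)
    well_center: tuple[float, float] = (256.0, 256.0)  # (x, y)
    well_radius_px: float = 220.0
    background_level: int = 18000
    well_level: int = 45000
    stain_spots: tuple[StainSpot, ...] = ()
    dirt_blobs: tuple[DirtBlob, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    pixel_size_um: float = 1.0
    bit_depth: int = 16
    dye_name: str = "alizarin_red_s"  # dye whose truth mask is derived

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 1 or w < 1:
            raise ValueError("image size must be positive")
        maxval = 2**self.bit_depth - 1
        if not 0 <= self.background_level <= maxval or not 0 < self.well_level <= maxval:
            raise ValueError(f"levels must lie within [0, {maxval}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dye_name not in _TRUTH_DYES:
            raise ValueError(f"unknown dye {self.dye_name!r}")
        for s in self.stain_spots:
            if (
                s.center_x - s.radius < 0
                or s.center_x + s.radius > w
                or s.center_y - s.radius < 0
                or s.center_y + s.radius > h
            ):
                raise ValueError(
                    f"stain spot at ({s.center_x}, {s.center_y}) r={s.radius} "
                    f"extends outside the {w}x{h} image"
                )


@dataclass
class GroundTruth:
    """Exact per-pixel truth of a generated well."""

    positive_mask: np.ndarray
    well_circle: CircularROI
    spheroid_mask: np.ndarray | None = None


def _disc_amount(shape: tuple[int, int], cx: float, cy: float, radius: float, falloff: float) -> np.ndarray:
    """Mixing amount per pixel: 1 inside the flat top, linear to 0 at radius."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.sqrt((xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2)
    if falloff <= 0:
        return (d <= radius).astype(np.float64)
    flat = radius - falloff
    amt = np.clip((radius - d) / falloff, 0.0, 1.0)
    amt[d <= flat] = 1.0
    return amt


def _stain_target_levels(dye_name: str, well_level: float, ratio: float) -> dict[str, float]:
    """Channel levels of a fully stained pixel hitting the target ratio."""
    if dye_name in ("alizarin_red_s", "oil_red_o"):
        # red kept at well level, complements suppressed: r/(g+b) = ratio
        return {"red": well_level, "green": well_level / (2 * ratio), "blue": well_level / (2 * ratio)}
    # alcian blue: green/blue kept, red suppressed: (g+b)/r = ratio
    return {"red": 2 * well_level / ratio, "green": well_level, "blue": well_level}


def _truth_loop(
    red: np.ndarray, green: np.ndarray, blue: np.ndarray, dye_name: str
) -> np.ndarray:
    """Independent per-pixel classification of the noiseless image."""
    signal, complement, threshold = _TRUTH_DYES[dye_name]
    chans = {"red": red.tolist(), "green": green.tolist(), "blue": blue.tolist()}
    sig_rows = [chans[c] for c in signal]
    comp_rows = [chans[c] for c in complement]
    h, w = red.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        srows = [rows[i] for rows in sig_rows]
        crows = [rows[i] for rows in comp_rows]
        orow = out[i]
        for j in range(w):
            denom = 0.0
            for row in crows:
                denom += row[j]
            if denom <= 0.0:
                continue
            num = 0.0
            for row in srows:
                num += row[j]
            if num / denom >= threshold:
                orow[j] = True
    return out


def generate_well(spec: SyntheticWellSpec) -> tuple[ColorComposite, GroundTruth]:
    """Render a synthetic well scan and its exact ground truth.

    The noiseless image (integers, after rounding) defines the truth mask
    via the independent per-pixel loop; Gaussian noise of sd ``noise_sd``
    intensity counts is then added per channel and clipped to the valid
    range, so the truth is unaffected by the noise realisation.
    """
    h, w = spec.image_size_px
    maxval = 2**spec.bit_depth - 1
    cx, cy = spec.well_center

    base = np.full((h, w), float(spec.background_level))
    well = _disc_amount((h, w), cx, cy, spec.well_radius_px, 0.0).astype(bool)
    planes = {ch: base.copy() for ch in ("red", "green", "blue")}
    for ch in planes:
        planes[ch][well] = float(spec.well_level)

    for spot in spec.stain_spots:
        amt = _disc_amount((h, w), spot.center_x, spot.center_y, spot.radius, spot.edge_falloff_px)
        target = _stain_target_levels(spot.dye_name, float(spec.well_level), spot.ratio)
        for ch in planes:
            planes[ch] = planes[ch] * (1 - amt) + target[ch] * amt

    for blob in spec.dirt_blobs:
        inside = _disc_amount((h, w), blob.center_x, blob.center_y, blob.radius, 0.0).astype(bool)
        for ch, factor in zip(("red", "green", "blue"), blob.hue):
            planes[ch][inside] *= factor

    noiseless = {
        ch: np.clip(np.rint(arr), 0, maxval).astype(np.uint16) for ch, arr in planes.items()
    }
    truth_mask = _truth_loop(
        noiseless["red"].astype(np.float64),
        noiseless["green"].astype(np.float64),
        noiseless["blue"].astype(np.float64),
        spec.dye_name,
    )

    rng = np.random.default_rng(spec.seed)
    final = {}
    for ch in ("red", "green", "blue"):
        arr = noiseless[ch].astype(np.float64)
        if spec.noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd, size=arr.shape)
        final[ch] = np.clip(np.rint(arr), 0, maxval).astype(np.uint16)

    composite = composite_from_arrays(
        final["red"], final["green"], final["blue"],
        pixel_size_um=spec.pixel_size_um, bit_depth=spec.bit_depth,
    )
    truth = GroundTruth(
        positive_mask=truth_mask,
        well_circle=CircularROI(center_x=cx, center_y=cy, radius=spec.well_radius_px),
    )
    return composite, truth


def generate_tiles(mosaic: ColorComposite, grid: TileGridSpec) -> list[ColorComposite]:
    """Crop a mosaic into an overlapping row-major tile grid.

    The crops respect the grid's overlaps, so stitching them back under
    the overwrite policy reconstructs the mosaic bit-exactly.
    """
    h, w = mosaic.shape
    if (h, w) != (grid.mosaic_height_px, grid.mosaic_width_px):
        raise ValueError(
            f"mosaic shape {(h, w)} inconsistent with grid "
            f"({grid.mosaic_height_px}, {grid.mosaic_width_px})"
        )
    tiles = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x0 = c * (grid.tile_width_px - grid.overlap_x_px)
            y0 = r * (grid.tile_height_px - grid.overlap_y_px)
            tiles.append(
                ColorComposite(
                    red=ChannelPlane(
                        mosaic.red.pixels[y0 : y0 + grid.tile_height_px, x0 : x0 + grid.tile_width_px].copy(),
                        Channel.RED, mosaic.red.bit_depth, grid.pixel_size_um,
                    ),
                    green=ChannelPlane(
                        mosaic.green.pixels[y0 : y0 + grid.tile_height_px, x0 : x0 + grid.tile_width_px].copy(),
                        Channel.GREEN, mosaic.green.bit_depth, grid.pixel_size_um,
                    ),
                    blue=ChannelPlane(
                        mosaic.blue.pixels[y0 : y0 + grid.tile_height_px, x0 : x0 + grid.tile_width_px].copy(),
                        Channel.BLUE, mosaic.blue.bit_depth, grid.pixel_size_um,
                    ),
                    float_promoted=mosaic.float_promoted,
                )
            )
    return tiles


def generate_spheroid_section(
    image_size_px: tuple[int, int] = (256, 256),
    body_center: tuple[float, float] = (128.0, 128.0),
    body_radius_px: float = 80.0,
    stained_radius_px: float = 0.0,
    dye_name: str = "alcian_blue_8gx",
    stain_ratio: float = 6.0,
    background_level: int = 55000,
    body_level: int = 15000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ColorComposite, np.ndarray, np.ndarray]:
    """Render one spheroid cross section: a dark tissue disc on a bright
    background with an optional concentric stained core.

    Returns ``(composite, body_mask, positive_mask)`` where both masks are
    the exact pixel-center-rule discs of the noiseless image.
    """
    h, w = image_size_px
    cx, cy = body_center
    body = _disc_amount((h, w), cx, cy, body_radius_px, 0.0).astype(bool)
    planes = {ch: np.full((h, w), float(background_level)) for ch in ("red", "green", "blue")}
    for ch in planes:
        planes[ch][body] = float(body_level)
    stained = np.zeros((h, w), dtype=bool)
    if stained_radius_px > 0:
        stained = _disc_amount((h, w), cx, cy, stained_radius_px, 0.0).astype(bool) & body
        target = _stain_target_levels(dye_name, float(body_level), stain_ratio)
        for ch in planes:
            planes[ch][stained] = target[ch]
    maxval = 65535
    noiseless = {ch: np.clip(np.rint(a), 0, maxval).astype(np.uint16) for ch, a in planes.items()}
    positive = _truth_loop(
        noiseless["red"].astype(np.float64),
        noiseless["green"].astype(np.float64),
        noiseless["blue"].astype(np.float64),
        dye_name,
    ) & body
    rng = np.random.default_rng(seed)
    final = {}
    for ch in ("red", "green", "blue"):
        arr = noiseless[ch].astype(np.float64)
        if noise_sd > 0:
            arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
        final[ch] = np.clip(np.rint(arr), 0, maxval).astype(np.uint16)
    composite = composite_from_arrays(final["red"], final["green"], final["blue"])
    return composite, body, positive


def generate_time_course(
    rates: Mapping[str, float],
    timepoints_days: Sequence[float] = (14.0, 17.0, 21.0),
    n_replicates: int = 3,
    rel_noise_sd: float = 0.0,
    seed: int = 0,
    lineage: str = "osteogenic",
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate a differentiation time course: value = rate x day + noise.

    Per line and timepoint, ``n_replicates`` replicate values are drawn as
    ``rate * day * (1 + N(0, rel_noise_sd))``, floored at 0 (noise sd is
    relative to the true value).  Returns the replicate table (columns
    well_id, cell_line, lineage, condition, timepoint_days,
    positive_count) and the true ranking: lines ordered by
    ``sum(rate * day)`` descending, ties broken lexicographically.
    """
    if any(r < 0 for r in rates.values()):
        raise ValueError("growth rates must be non-negative")
    if rel_noise_sd < 0:
        raise ValueError("rel_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for line in sorted(rates):
        rate = rates[line]
        for t in timepoints_days:
            true = rate * t
            for rep in range(n_replicates):
                noise = rng.normal(0.0, rel_noise_sd) if rel_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "well_id": f"{line}_d{t:g}_r{rep + 1}",
                        "cell_line": line,
                        "lineage": lineage,
                        "condition": "differentiated",
                        "timepoint_days": float(t),
                        "positive_count": max(0.0, true * (1.0 + noise)),
                    }
                )
    table = pd.DataFrame(rows)
    totals = {line: sum(rates[line] * t for t in timepoints_days) for line in rates}
    true_ranking = sorted(totals, key=lambda k: (-totals[k], k))
    return table, true_ranking
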