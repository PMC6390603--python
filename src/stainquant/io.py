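"""Per-channel image I/O, composites, bit-depth promotion, and tile stitching.

Whole-well bright-field scans are acquired one illumination channel at a
time (red, green, blue LEDs), each stored as a single-channel 16-bit
raster.  This module reads such channel triples into a
:class:`ColorComposite`, promotes them to floating point so that channel
sums cannot saturate, and stitches tile grids (with stated physical
overlaps) into whole-well mosaics.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile

log = logging.getLogger(__name__)

__all__ = [
    "Channel",
    "ChannelPlane",
    "ColorComposite",
    "TileGridSpec",
    "GRID_24_WELL",
    "GRID_48_WELL",
    "DimensionMismatchError",
    "FormatError",
    "read_plane",
    "read_composite",
    "write_plane",
    "write_composite",
    "promote_to_float",
    "stitch_tiles",
]


class Channel(str, enum.Enum):
    """Illumination channel of a single-channel acquisition."""

    RED = "red"
    GREEN = "green"
    BLUE = "blue"


class DimensionMismatchError(ValueError):
    """Raised when channel planes or tiles do not share dimensions."""


class FormatError(ValueError):
    """Raised when an input file is not a single-channel raster."""


@dataclass
class ChannelPlane:
    """One single-channel intensity plane of a well or spheroid scan.

    Parameters
    ----------
    pixels
        2-D non-negative integer (or, after promotion, float) intensity grid.
    channel
        Which illumination channel the plane records.
    bit_depth
        Bits per pixel of the source camera; values must lie in
        ``[0, 2**bit_depth - 1]`` for integer planes.
    pixel_size_um
        Physical edge length of one pixel, in micrometres.
    """

    pixels: np.ndarray
    channel: Channel
    bit_depth: int = 16
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(
                f"channel plane must be a non-empty 2-D grid, got shape {self.pixels.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.bit_depth <= 0:
            raise ValueError("bit_depth must be positive")
        if np.issubdtype(self.pixels.dtype, np.integer):
            lo, hi = int(self.pixels.min()), int(self.pixels.max())
            if lo < 0 or hi > 2**self.bit_depth - 1:
                raise ValueError(
                    f"pixel values [{lo}, {hi}] outside [0, {2**self.bit_depth - 1}] "
                    f"for bit depth {self.bit_depth}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ColorComposite:
    """Three co-registered channel planes of one well or spheroid section."""

    red: ChannelPlane
    green: ChannelPlane
    blue: ChannelPlane
    float_promoted: bool = False

    def __post_init__(self) -> None:
        shapes = {self.red.shape, self.green.shape, self.blue.shape}
        if len(shapes) != 1:
            raise DimensionMismatchError(
                f"channel planes differ in shape: red {self.red.shape}, "
                f"green {self.green.shape}, blue {self.blue.shape}"
            )
        sizes = {self.red.pixel_size_um, self.green.pixel_size_um, self.blue.pixel_size_um}
        if len(sizes) != 1:
            raise ValueError(f"channel planes differ in pixel_size_um: {sizes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def pixel_size_um(self) -> float:
        return self.red.pixel_size_um

    def plane(self, channel: Channel | str) -> ChannelPlane:
        return {Channel.RED: self.red, Channel.GREEN: self.green, Channel.BLUE: self.blue}[
            Channel(channel)
        ]

    def channel_sum(self) -> np.ndarray:
        """Sum of the three channel planes as float64 (transmission proxy)."""
        return (
            self.red.pixels.astype(np.float64)
            + self.green.pixels.astype(np.float64)
            + self.blue.pixels.astype(np.float64)
        )


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (overlaps are >= 0)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class TileGridSpec:
    """Geometry of a rectangular tile acquisition with physical overlaps.

    The default presets mirror common whole-well scans: a 24-well plate
    needs a 9 (horizontal) x 13 (vertical) grid, a 48-well plate 7 x 10,
    both with 200 um horizontal and 250 um vertical overlap.
    """

    n_cols: int
    n_rows: int
    tile_width_px: int
    tile_height_px: int
    pixel_size_um: float
    overlap_x_um: float = 200.0
    overlap_y_um: float = 250.0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.tile_width_px < 1 or self.tile_height_px < 1:
            raise ValueError("tile dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.overlap_x_um < 0 or self.overlap_y_um < 0:
            raise ValueError("overlaps must be non-negative")
        if self.overlap_x_px >= self.tile_width_px:
            raise ValueError(
                f"horizontal overlap {self.overlap_x_px} px must be smaller than "
                f"tile width {self.tile_width_px} px"
            )
        if self.overlap_y_px >= self.tile_height_px:
            raise ValueError(
                f"vertical overlap {self.overlap_y_px} px must be smaller than "
                f"tile height {self.tile_height_px} px"
            )

    @property
    def overlap_x_px(self) -> int:
        return _round_half_away(self.overlap_x_um / self.pixel_size_um)

    @property
    def overlap_y_px(self) -> int:
        return _round_half_away(self.overlap_y_um / self.pixel_size_um)

    @property
    def mosaic_width_px(self) -> int:
        return self.n_cols * self.tile_width_px - (self.n_cols - 1) * self.overlap_x_px

    @property
    def mosaic_height_px(self) -> int:
        return self.n_rows * self.tile_height_px - (self.n_rows - 1) * self.overlap_y_px


def GRID_24_WELL(tile_width_px: int, tile_height_px: int, pixel_size_um: float) -> TileGridSpec:
    """9 x 13 tile grid preset (one well of a 24-well plate)."""
    return TileGridSpec(9, 13, tile_width_px, tile_height_px, pixel_size_um)


def GRID_48_WELL(tile_width_px: int, tile_height_px: int, pixel_size_um: float) -> TileGridSpec:
    """7 x 10 tile grid preset (one well of a 48-well plate)."""
    return TileGridSpec(7, 10, tile_width_px, tile_height_px, pixel_size_um)


# ---------------------------------------------------------------------------
# file I/O


def _read_raster(path: Path | str) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"channel file not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path} decodes to shape {arr.shape}; expected a single-channel 2-D "
            "raster (one file per illumination channel, not an RGB image)"
        )
    return arr


def _infer_bit_depth(arr: np.ndarray, path: Path | str) -> int:
    if arr.dtype == np.uint8:
        log.warning("%s is 8-bit; treating bit_depth=8 (ratio thresholds are bit-depth independent)", path)
        return 8
    return 16


def read_plane(path: Path | str, channel: Channel | str, pixel_size_um: float = 1.0) -> ChannelPlane:
    """Read one single-channel raster (16-bit TIFF/PNG; 8-bit accepted with a warning)."""
    arr = _read_raster(path)
    return ChannelPlane(
        pixels=arr,
        channel=Channel(channel),
        bit_depth=_infer_bit_depth(arr, path),
        pixel_size_um=pixel_size_um,
    )


def read_composite(
    red_path: Path | str,
    green_path: Path | str,
    blue_path: Path | str,
    pixel_size_um: float = 1.0,
) -> ColorComposite:
    """Read a channel-file triple into a composite, preserving values bit-exactly."""
    red = read_plane(red_path, Channel.RED, pixel_size_um)
    green = read_plane(green_path, Channel.GREEN, pixel_size_um)
    blue = read_plane(blue_path, Channel.BLUE, pixel_size_um)
    return ColorComposite(red=red, green=green, blue=blue, float_promoted=False)


def write_plane(plane: ChannelPlane, path: Path | str) -> None:
    """Write one channel plane as a single-channel raster (TIFF or PNG)."""
    path = Path(path)
    dtype = np.uint8 if plane.bit_depth <= 8 else np.uint16
    arr = plane.pixels.astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def write_composite(composite: ColorComposite, path: Path | str) -> None:
    """Write a composite as a 3-plane 16-bit TIFF (audit copy of the original data)."""
    if composite.float_promoted:
        raise ValueError("write pre-promotion composites only; audit images keep raw integers")
    stack = np.stack(
        [composite.red.pixels, composite.green.pixels, composite.blue.pixels]
    ).astype(np.uint16)
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


# ---------------------------------------------------------------------------
# promotion and stitching


def promote_to_float(composite: ColorComposite) -> ColorComposite:
    """Promote a composite to 32-bit+ floating point to avoid pixel saturation.

    After promotion, sums of two 16-bit values (max 131070) are represented
    exactly and never clamp at the integer ceiling.  Idempotent: promoting a
    promoted composite returns an equal composite.
    """
    if composite.float_promoted:
        log.debug("composite already float-promoted; promotion is a no-op")
        return composite

    def _promote(plane: ChannelPlane) -> ChannelPlane:
        return replace(plane, pixels=plane.pixels.astype(np.float64))

    return ColorComposite(
        red=_promote(composite.red),
        green=_promote(composite.green),
        blue=_promote(composite.blue),
        float_promoted=True,
    )


def _stitch_plane(
    tiles: Sequence[np.ndarray],
    grid: TileGridSpec,
    policy: Literal["overwrite", "crop-half"],
) -> np.ndarray:
    out = np.zeros((grid.mosaic_height_px, grid.mosaic_width_px), dtype=tiles[0].dtype)
    ox, oy = grid.overlap_x_px, grid.overlap_y_px
    tw, th = grid.tile_width_px, grid.tile_height_px
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            tile = tiles[r * grid.n_cols + c]
            x0 = c * (tw - ox)
            y0 = r * (th - oy)
            if policy == "overwrite":
                out[y0 : y0 + th, x0 : x0 + tw] = tile
            else:  # crop-half: split each overlap evenly between neighbours
                lx = ox // 2 if c > 0 else 0
                ty = oy // 2 if r > 0 else 0
                rx = ox - ox // 2 if c < grid.n_cols - 1 else 0
                by = oy - oy // 2 if r < grid.n_rows - 1 else 0
                out[y0 + ty : y0 + th - by, x0 + lx : x0 + tw - rx] = tile[
                    ty : th - by, lx : tw - rx
                ]
    return out


def stitch_tiles(
    tiles: Sequence[ColorComposite],
    grid: TileGridSpec,
    policy: Literal["overwrite", "crop-half"] = "overwrite",
) -> ColorComposite:
    """Stitch a row-major grid of tile composites into one whole-well mosaic.

    Tiles are ordered left-to-right, top-to-bottom; the origin is the
    top-left pixel.  Output width is ``n_cols*tile_w - (n_cols-1)*overlap_x_px``
    and analogously for height.  Under the default ``overwrite`` policy the
    tile placed later in row-major order wins inside overlap regions, which
    makes stitching the exact inverse of overlap-respecting tile cropping.
    """
    if len(tiles) != grid.n_cols * grid.n_rows:
        raise ValueError(
            f"expected {grid.n_cols * grid.n_rows} tiles for a "
            f"{grid.n_cols}x{grid.n_rows} grid, got {len(tiles)}"
        )
    expected = (grid.tile_height_px, grid.tile_width_px)
    for i, t in enumerate(tiles):
        if t.shape != expected:
            raise DimensionMismatchError(
                f"tile {i} has shape {t.shape}, grid expects {expected}"
            )
        if t.pixel_size_um != grid.pixel_size_um:
            raise ValueError(
                f"tile {i} pixel_size_um {t.pixel_size_um} != grid {grid.pixel_size_um}"
            )
    promoted = tiles[0].float_promoted
    planes = {}
    for ch in Channel:
        arrays = [t.plane(ch).pixels for t in tiles]
        stitched = _stitch_plane(arrays, grid, policy)
        planes[ch] = ChannelPlane(
            pixels=stitched,
            channel=ch,
            bit_depth=tiles[0].plane(ch).bit_depth,
            pixel_size_um=grid.pixel_size_um,
        )
    return ColorComposite(
        red=planes[Channel.RED],
        green=planes[Channel.GREEN],
        blue=planes[Channel.BLUE],
        float_promoted=promoted,
    )


def composite_from_arrays(
    red: np.ndarray,
    green: np.ndarray,
    blue: np.ndarray,
    pixel_size_um: float = 1.0,
    bit_depth: int = 16,
) -> ColorComposite:
    """Convenience constructor from three raw arrays (integer, unpromoted)."""
    return ColorComposite(
        red=ChannelPlane(red, Channel.RED, bit_depth, pixel_size_um),
        green=ChannelPlane(green, Channel.GREEN, bit_depth, pixel_size_um),
        blue=ChannelPlane(blue, Channel.BLUE, bit_depth, pixel_size_um),
    )
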