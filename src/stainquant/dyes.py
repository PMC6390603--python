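"""Dye specifications and channel-ratio positive-pixel classification.

The core of the method: a histological dye absorbs its complementary
colour, so under separate red/green/blue LED illumination a stained pixel
shows high transmission in its signal channel(s) and low transmission in
the complementary channel(s).  Positivity is decided on the per-pixel
ratio

    (sum of signal-channel intensities) / (sum of complement-channel intensities)

with an inclusive threshold.  Built-in dyes:

* Alizarin Red S (calcium, osteogenesis) — red / (green + blue) >= 1
* Oil Red O (lipid droplets, adipogenesis) — red / (green + blue) >= 1
* Alcian Blue 8GX (cartilage matrix, chondrogenesis) — (green + blue) / red >= 4

Because the statistic is a ratio of intensities it is homogeneous of
degree zero: rescaling all channels by a common factor (a bit-depth or
exposure change) leaves the classification unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Channel, ColorComposite

__all__ = [
    "DyeSpec",
    "RatioImage",
    "ALIZARIN_RED_S",
    "OIL_RED_O",
    "ALCIAN_BLUE_8GX",
    "BUILTIN_DYES",
    "NotPromotedError",
    "ratio_map",
    "classify_positive",
]


class NotPromotedError(ValueError):
    """Raised when ratio computation is attempted on an unpromoted composite."""


@dataclass(frozen=True)
class DyeSpec:
    """A dye's signal channels, complementary channels, and positivity threshold.

    ``signal_channels`` and ``complement_channels`` are disjoint, non-empty
    subsets of {red, green, blue}; a pixel is positive when the summed
    signal intensity is at least ``threshold`` times the summed complement
    intensity.
    """

    name: str
    signal_channels: frozenset[Channel]
    complement_channels: frozenset[Channel]
    threshold: float

    def __post_init__(self) -> None:
        sig = frozenset(Channel(c) for c in self.signal_channels)
        comp = frozenset(Channel(c) for c in self.complement_channels)
        object.__setattr__(self, "signal_channels", sig)
        object.__setattr__(self, "complement_channels", comp)
        if not sig or not comp:
            raise ValueError("signal and complement channel sets must be non-empty")
        if sig & comp:
            raise ValueError(f"signal and complement channels overlap: {sorted(c.value for c in sig & comp)}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


ALIZARIN_RED_S = DyeSpec(
    name="Alizarin Red S",
    signal_channels=frozenset({Channel.RED}),
    complement_channels=frozenset({Channel.GREEN, Channel.BLUE}),
    threshold=1.0,
)

OIL_RED_O = DyeSpec(
    name="Oil Red O",
    signal_channels=frozenset({Channel.RED}),
    complement_channels=frozenset({Channel.GREEN, Channel.BLUE}),
    threshold=1.0,
)

ALCIAN_BLUE_8GX = DyeSpec(
    name="Alcian Blue 8GX",
    signal_channels=frozenset({Channel.GREEN, Channel.BLUE}),
    complement_channels=frozenset({Channel.RED}),
    threshold=4.0,
)

BUILTIN_DYES: dict[str, DyeSpec] = {
    "alizarin_red_s": ALIZARIN_RED_S,
    "oil_red_o": OIL_RED_O,
    "alcian_blue_8gx": ALCIAN_BLUE_8GX,
}


@dataclass
class RatioImage:
    """Per-pixel signal/complement ratio with a mask of undefined pixels.

    ``undefined_mask`` marks zero-denominator pixels: no transmitted
    complementary light means no reliable ratio, so those pixels are
    excluded from positivity rather than propagated as inf/NaN.
    """

    values: np.ndarray
    dye: DyeSpec
    undefined_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.undefined_mask.shape:
            raise ValueError("values and undefined_mask must share shape")


def ratio_map(composite: ColorComposite, dye: DyeSpec) -> RatioImage:
    """Compute the dye's signal/complement ratio image.

    Requires a float-promoted composite so that channel sums (up to twice
    the integer ceiling) cannot clamp.
    """
    if not composite.float_promoted:
        raise NotPromotedError(
            "composite must be float-promoted before ratio computation; "
            "call promote_to_float() first (guards against saturation of channel sums)"
        )
    signal = np.zeros(composite.shape, dtype=np.float64)
    for ch in dye.signal_channels:
        signal += composite.plane(ch).pixels
    complement = np.zeros(composite.shape, dtype=np.float64)
    for ch in dye.complement_channels:
        complement += composite.plane(ch).pixels
    undefined = complement == 0
    values = np.zeros_like(signal)
    np.divide(signal, complement, out=values, where=~undefined)
    return RatioImage(values=values, dye=dye, undefined_mask=undefined)


def classify_positive(
    ratio: RatioImage, roi_mask: np.ndarray
) -> tuple[np.ndarray, int]:
    """Classify positive pixels within the region of interest.

    A pixel is positive iff its ratio is >= the dye threshold (inclusive
    boundary), it lies inside ``roi_mask``, and its ratio is defined.
    Returns the boolean positive mask and the positive-pixel count.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != ratio.values.shape:
        raise ValueError(
            f"ROI mask shape {roi_mask.shape} does not match ratio image {ratio.values.shape}"
        )
    positive = (ratio.values >= ratio.dye.threshold) & roi_mask & ~ratio.undefined_mask
    return positive, int(np.count_nonzero(positive))
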