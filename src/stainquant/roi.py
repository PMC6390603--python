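"""Region-of-interest construction: circular well masks and spheroid bodies.

The analyzed region is either the circular well bottom (fixed geometry or
detected from the bright well disc) or, for 3-D chondrogenic cultures, the
spheroid body on a stained cross section (tissue absorbs light, so the
body is the dark region on the bright background).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops

from .io import ColorComposite

__all__ = [
    "MaskSource",
    "CircularROI",
    "RegionMask",
    "DetectionError",
    "circle_to_mask",
    "detect_well_roi",
    "spheroid_mask",
]


class DetectionError(RuntimeError):
    """Raised when automatic ROI detection fails; supply a manual ROI instead."""


class MaskSource(str, enum.Enum):
    CIRCLE = "circle"
    DETECTED_WELL = "detected_well"
    SPHEROID = "spheroid"
    FULL_IMAGE = "full_image"


@dataclass(frozen=True)
class CircularROI:
    """A circular analysis region in pixel coordinates (may clip the image border)."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class RegionMask:
    """Boolean analysis mask over an image, tagged with its provenance."""

    mask: np.ndarray
    source: MaskSource

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def pixel_count(self) -> int:
        return int(np.count_nonzero(self.mask))


def circle_to_mask(circle: CircularROI, shape: tuple[int, int]) -> RegionMask:
    """Rasterize a circle: pixel (i, j) is in iff its center (j+0.5, i+0.5)
    lies within ``radius`` of the circle center."""
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError("shape must be positive")
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx + 0.5 - circle.center_x) ** 2 + (yy + 0.5 - circle.center_y) ** 2
    return RegionMask(mask=d2 <= circle.radius**2, source=MaskSource.CIRCLE)


def _channel_sum(composite: ColorComposite) -> np.ndarray:
    return composite.channel_sum()


def otsu_threshold(values: np.ndarray, nbins: int = 512) -> float:
    """Otsu's between-class-variance threshold on a 512-bin histogram.

    Returns the upper EDGE of the optimal threshold bin, so the dark class
    is exactly ``values < threshold`` and the bright class
    ``values >= threshold``.  (A bin-center convention can misassign an
    entire intensity level that sits above its bin center, which matters
    for the spiky histograms of flat synthetic fixtures.)
    """
    hist, edges = np.histogram(values.ravel(), bins=nbins)
    hist = hist.astype(np.float64)
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    sum0 = np.cumsum(hist * centers)
    m0 = np.divide(sum0, w0, out=np.zeros_like(sum0), where=w0 > 0)
    sum1 = sum0[-1] - sum0
    m1 = np.divide(sum1, w1, out=np.zeros_like(sum1), where=w1 > 0)
    var = w0[:-1] * w1[:-1] * (m0[:-1] - m1[:-1]) ** 2
    k = int(np.argmax(var))
    return float(edges[k + 1])


def detect_well_roi(
    composite: ColorComposite,
    expected_radius_px: float,
    tolerance_fraction: float = 0.2,
) -> CircularROI:
    """Detect the bright circular well region against its darker surround.

    Thresholds the channel-sum image (Otsu), keeps the largest connected
    bright component, and returns its centroid with the equivalent-area
    radius.  Fails if no component's radius lies within
    ``tolerance_fraction`` of ``expected_radius_px``; pass a manual
    :class:`CircularROI` in that case.
    """
    total = _channel_sum(composite)
    if total.max() == total.min():
        raise DetectionError(
            "image is uniform; cannot detect a well — supply a manual circular ROI"
        )
    bright = total >= otsu_threshold(total)
    # stained regions absorb light and can dip below the Otsu cut; fill
    # holes so they do not bite into the detected well disc
    bright = ndimage.binary_fill_holes(bright)
    labels = label(bright)
    props = regionprops(labels)
    if not props:
        raise DetectionError("no bright component found — supply a manual circular ROI")
    largest = max(props, key=lambda p: p.area)
    radius = float(np.sqrt(largest.area / np.pi))
    if abs(radius - expected_radius_px) > tolerance_fraction * expected_radius_px:
        raise DetectionError(
            f"largest bright component has equivalent radius {radius:.1f} px, "
            f"outside {tolerance_fraction:.0%} of expected {expected_radius_px:.1f} px "
            "— supply a manual circular ROI"
        )
    cy, cx = largest.centroid
    # regionprops centroid is in index coordinates; shift to pixel-center frame
    return CircularROI(center_x=cx + 0.5, center_y=cy + 0.5, radius=radius)


def spheroid_mask(composite: ColorComposite) -> RegionMask:
    """Segment the spheroid body on a bright-field cross section.

    Tissue absorbs light, so body pixels have channel-sum transmission
    below an Otsu-chosen background threshold.  Holes are filled and the
    largest connected component is retained; its pixel count is the
    denominator of the per-section stained fraction.
    """
    total = _channel_sum(composite)
    if total.max() == total.min():
        raise DetectionError("image is uniform; no tissue section found")
    dark = total < otsu_threshold(total)
    if not dark.any():
        raise DetectionError("no tissue pixels below background threshold")
    filled = ndimage.binary_fill_holes(dark)
    labels = label(filled)
    props = regionprops(labels)
    if not props:
        raise DetectionError("no connected tissue component found")
    largest = max(props, key=lambda p: p.area)
    return RegionMask(mask=labels == largest.label, source=MaskSource.SPHEROID)
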