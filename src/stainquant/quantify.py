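"""Per-well and per-spheroid quantitative readouts and time-course tables.

All pixels inside the region of interest whose channel ratio meets the dye
threshold are counted; the readouts are the positive pixel count, the area
fraction (positive / ROI pixels), and the physical positive area in um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dyes import DyeSpec, classify_positive, ratio_map
from .io import ColorComposite, promote_to_float
from .roi import RegionMask, spheroid_mask

__all__ = [
    "WellMeta",
    "QuantResult",
    "SpheroidResult",
    "quantify_well",
    "quantify_spheroid",
    "assemble_time_course",
]


@dataclass(frozen=True)
class WellMeta:
    """Identifying metadata of one well at one timepoint."""

    well_id: str = ""
    cell_line: str = ""
    lineage: str = ""
    condition: str = ""  # "differentiated" or "control"
    timepoint_days: float = float("nan")


@dataclass(frozen=True)
class QuantResult:
    """Positive-pixel quantification of one well at one timepoint."""

    positive_count: int
    roi_count: int
    area_fraction: float
    positive_area_um2: float
    dye: str
    meta: WellMeta = field(default_factory=WellMeta)

    def __post_init__(self) -> None:
        if not 0 <= self.positive_count <= self.roi_count:
            raise ValueError("positive_count must lie in [0, roi_count]")

    def as_row(self) -> dict:
        return {
            "well_id": self.meta.well_id,
            "cell_line": self.meta.cell_line,
            "lineage": self.meta.lineage,
            "condition": self.meta.condition,
            "timepoint_days": self.meta.timepoint_days,
            "dye": self.dye,
            "positive_count": self.positive_count,
            "roi_count": self.roi_count,
            "area_fraction": self.area_fraction,
            "positive_area_um2": self.positive_area_um2,
        }


@dataclass(frozen=True)
class SpheroidResult:
    """Stained fraction of a spheroid pooled over its cross sections.

    The pooled fraction is total positive pixels over total spheroid
    pixels (a pixel-weighted pooling), not the unweighted mean of the
    per-section fractions.
    """

    per_section: tuple[tuple[int, int], ...]  # (positive_count, spheroid_count)
    pooled_fraction: float

    @property
    def section_fractions(self) -> tuple[float, ...]:
        return tuple(p / t for p, t in self.per_section)


def quantify_well(
    composite: ColorComposite,
    roi: RegionMask | np.ndarray,
    dye: DyeSpec,
    meta: WellMeta | None = None,
    return_mask: bool = False,
):
    """Quantify dye-positive pixels of one well inside the given ROI.

    The composite is float-promoted if necessary, the ratio image computed,
    and positive pixels counted inside the ROI.  Deterministic for fixed
    inputs.
    """
    mask = roi.mask if isinstance(roi, RegionMask) else np.asarray(roi, dtype=bool)
    roi_count = int(np.count_nonzero(mask))
    if roi_count == 0:
        raise ValueError("ROI is empty: no pixels to analyze")
    if not composite.float_promoted:
        composite = promote_to_float(composite)
    ratio = ratio_map(composite, dye)
    positive_mask, positive_count = classify_positive(ratio, mask)
    px_um = composite.pixel_size_um
    result = QuantResult(
        positive_count=positive_count,
        roi_count=roi_count,
        area_fraction=positive_count / roi_count,
        positive_area_um2=positive_count * px_um * px_um,
        dye=dye.name,
        meta=meta or WellMeta(),
    )
    if return_mask:
        return result, positive_mask
    return result


def quantify_spheroid(
    sections: Sequence[ColorComposite], dye: DyeSpec
) -> SpheroidResult:
    """Quantify stained fraction over the cross sections of one spheroid.

    Per section, the spheroid body mask supplies the denominator and the
    dye-positive pixels within it the numerator; sections are pooled as
    total positive over total spheroid pixels.
    """
    if not sections:
        raise ValueError("at least one spheroid section is required")
    per_section: list[tuple[int, int]] = []
    for i, section in enumerate(sections):
        try:
            body = spheroid_mask(section)
        except Exception as exc:
            raise ValueError(f"section {i}: spheroid segmentation failed: {exc}") from exc
        if body.pixel_count == 0:
            raise ValueError(f"section {i}: empty spheroid mask")
        promoted = section if section.float_promoted else promote_to_float(section)
        ratio = ratio_map(promoted, dye)
        _, positive = classify_positive(ratio, body.mask)
        per_section.append((positive, body.pixel_count))
    total_pos = sum(p for p, _ in per_section)
    total_px = sum(t for _, t in per_section)
    return SpheroidResult(
        per_section=tuple(per_section), pooled_fraction=total_pos / total_px
    )


def assemble_time_course(
    results: Sequence[QuantResult], value: str = "positive_count"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble replicate-level and summary time-course tables.

    Returns ``(replicates, summary)``: replicate rows are preserved as-is;
    the summary holds per (cell_line, lineage, condition, timepoint_days)
    mean and sample standard deviation (ddof=1; NaN for single replicates)
    of the chosen value column.  Duplicate (well_id, timepoint) pairs are
    rejected.
    """
    replicates = pd.DataFrame([r.as_row() for r in results])
    if replicates.empty:
        summary = pd.DataFrame(
            columns=["cell_line", "lineage", "condition", "timepoint_days", "mean", "sd", "n"]
        )
        return replicates, summary
    if value not in replicates.columns:
        raise ValueError(f"unknown value column {value!r}")
    dup = replicates.duplicated(subset=["well_id", "timepoint_days"])
    if dup.any():
        pairs = replicates.loc[dup, ["well_id", "timepoint_days"]].values.tolist()
        raise ValueError(f"duplicate (well_id, timepoint) entries: {pairs}")
    keys = ["cell_line", "lineage", "condition", "timepoint_days"]
    summary = (
        replicates.groupby(keys, dropna=False)[value]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )
    return replicates, summary
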