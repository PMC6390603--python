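"""Batch orchestration: run the quantification pipeline over many wells.

Every discovered well is read, promoted, masked, and quantified; failures
are logged and skipped (the run continues) but make the overall status
non-zero.  Output tables are sorted by (cell_line, lineage,
timepoint_days, well_id) so reruns and shuffled discovery orders produce
byte-identical CSVs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import promote_to_float, read_composite
from .quantify import QuantResult, WellMeta, quantify_well
from .ranking import ranking_table
from .roi import MaskSource, RegionMask, circle_to_mask, detect_well_roi, spheroid_mask

log = logging.getLogger(__name__)

__all__ = ["BatchOutcome", "run_batch"]

SORT_KEYS = ["cell_line", "lineage", "timepoint_days", "well_id"]


@dataclass
class BatchOutcome:
    """Results bundle of one batch run."""

    results: list[QuantResult]
    failures: list[tuple[str, str]]  # (well_id, reason)
    summary_csv: Path | None = None
    ranking_csv: Path | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


def _resolve_mask(config: RunConfig, composite) -> RegionMask:
    roi = config.roi
    if roi.mode == "circle":
        return circle_to_mask(roi.circle, composite.shape)
    if roi.mode == "detect":
        circle = detect_well_roi(composite, roi.expected_radius_px, roi.tolerance_fraction)
        mask = circle_to_mask(circle, composite.shape)
        return RegionMask(mask=mask.mask, source=MaskSource.DETECTED_WELL)
    if roi.mode == "spheroid":
        return spheroid_mask(composite)
    return RegionMask(mask=np.ones(composite.shape, dtype=bool), source=MaskSource.FULL_IMAGE)


def run_batch(config: RunConfig) -> BatchOutcome:
    """Quantify every configured well and write summary (and ranking) CSVs.

    Deterministic: identical config and inputs yield identical outputs.
    Individual well failures are logged and skipped, not fatal.
    """
    results: list[QuantResult] = []
    masks: list[tuple[str, np.ndarray]] = []
    failures: list[tuple[str, str]] = []
    for entry in config.wells:
        t0 = time.perf_counter()
        try:
            composite = read_composite(
                entry.red_path, entry.green_path, entry.blue_path, config.pixel_size_um
            )
            composite = promote_to_float(composite)
            mask = _resolve_mask(config, composite)
            meta = WellMeta(
                well_id=entry.well_id,
                cell_line=entry.cell_line,
                lineage=entry.lineage,
                condition=entry.condition,
                timepoint_days=entry.timepoint_days,
            )
            result, positive = quantify_well(
                composite, mask, config.dye_for(entry.dye), meta, return_mask=True
            )
            results.append(result)
            if config.write_masks:
                masks.append((entry.well_id, positive))
            log.info(
                "well=%s positive=%d roi=%d fraction=%.5f elapsed=%.2fs",
                entry.well_id, result.positive_count, result.roi_count,
                result.area_fraction, time.perf_counter() - t0,
            )
        except Exception as exc:
            failures.append((entry.well_id, str(exc)))
            log.error("well=%s FAILED: %s", entry.well_id, exc)

    outcome = BatchOutcome(results=results, failures=failures)
    if not results and not failures:
        raise ValueError("empty input set: no wells configured")

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame([r.as_row() for r in results])
    if not table.empty:
        table = table.sort_values(SORT_KEYS, kind="mergesort").reset_index(drop=True)
    summary_path = out_dir / "wells.csv"
    table.to_csv(summary_path, index=False)
    outcome.summary_csv = summary_path

    has_time_course = (
        not table.empty
        and table["timepoint_days"].notna().any()
        and (table["cell_line"] != "").any()
    )
    if has_time_course:
        ranking = ranking_table(
            table[table["timepoint_days"].notna()], value=config.value_column
        )
        ranking_path = out_dir / "ranking.csv"
        ranking.to_csv(ranking_path, index=False)
        outcome.ranking_csv = ranking_path

    if config.write_masks and masks:
        import imageio.v3 as iio

        mask_dir = out_dir / "masks"
        mask_dir.mkdir(exist_ok=True)
        for well_id, positive in masks:
            iio.imwrite(mask_dir / f"{well_id}_positive.png", positive.astype(np.uint8) * 255)

    return outcome
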