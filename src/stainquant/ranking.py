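"""Ranking Points, cell-line ranking, and image-vs-absorbance comparison statistics.

Lineage-specific differentiation potential is scored as "Ranking Points":
the per-timepoint measured values over the differentiation time course
(days 14, 17, 21) are summed and then divided by 1000 for image-based
quantification, or multiplied by 1000 for absorbance measurements.  The
scalings are pure presentation factors bringing both readouts to a
comparable magnitude; the induced ranking is scale-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ranking_points_dia",
    "ranking_points_absorbance",
    "RankedLine",
    "rank_lines",
    "signal_to_noise",
    "pearson_r",
    "total_stained_lipid_volume",
    "subtract_blank",
    "ranking_table",
]

#: timepoints (days of differentiation) entering the Ranking Points sum
DEFAULT_TIMEPOINTS_DAYS: tuple[float, ...] = (14.0, 17.0, 21.0)


def _check_values(values: Sequence[float], what: str) -> list[float]:
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError(f"{what}: at least one timepoint value is required")
    if any(v < 0 for v in vals):
        raise ValueError(f"{what}: values must be non-negative")
    return vals


def ranking_points_dia(timepoint_values: Sequence[float]) -> float:
    """Ranking Points from image-based quantification: sum of the
    per-timepoint values (replicate means), divided by 1000."""
    return sum(_check_values(timepoint_values, "ranking_points_dia")) / 1000.0


def ranking_points_absorbance(timepoint_values: Sequence[float]) -> float:
    """Ranking Points from absorbance: sum of the per-timepoint optical
    densities, multiplied by 1000."""
    return sum(_check_values(timepoint_values, "ranking_points_absorbance")) * 1000.0


@dataclass(frozen=True)
class RankedLine:
    """One cell line's position in a potency ranking (rank 1 = best)."""

    cell_line: str
    points: float
    rank: int
    tied: bool


def rank_lines(points: Mapping[str, float]) -> list[RankedLine]:
    """Rank cell lines by Ranking Points, descending (rank 1 = most potent).

    Ties are broken lexicographically by line name and flagged; the rank
    numbers remain a permutation of 1..n.
    """
    if not points:
        raise ValueError("at least one cell line is required")
    ordered = sorted(points.items(), key=lambda kv: (-kv[1], kv[0]))
    values = [v for _, v in ordered]
    out = []
    for i, (line, pts) in enumerate(ordered):
        tied = (i > 0 and values[i - 1] == pts) or (i + 1 < len(values) and values[i + 1] == pts)
        out.append(RankedLine(cell_line=line, points=pts, rank=i + 1, tied=tied))
    return out


def signal_to_noise(
    differentiated_values: Sequence[float], control_values: Sequence[float]
) -> float:
    """Assay signal-to-noise: mean of differentiated wells over mean of
    undifferentiated controls.  A zero control mean with positive signal
    yields ``inf`` (flagged infinite ratio)."""
    if len(differentiated_values) == 0 or len(control_values) == 0:
        raise ValueError("both groups must be non-empty")
    sig = float(np.mean(differentiated_values))
    noise = float(np.mean(control_values))
    if noise == 0:
        return math.inf if sig > 0 else math.nan
    return sig / noise


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation between two equal-length samples.

    Implemented from the closed form sum((x-mx)(y-my)) / (sx * sy); both
    samples need length >= 3 and non-zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("at least 3 paired observations are required")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt(np.sum(dx * dx)))
    sy = float(np.sqrt(np.sum(dy * dy)))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r = float(np.sum(dx * dy)) / (sx * sy)
    return max(-1.0, min(1.0, r))


def total_stained_lipid_volume(n_cells: int, per_cell_volume_ul: float) -> float:
    """Total stained lipid volume (ul) if every cell became an adipocyte:
    cell count times mean single-adipocyte volume (about 0.0003 ul)."""
    if n_cells < 0 or per_cell_volume_ul < 0:
        raise ValueError("cell count and per-cell volume must be non-negative")
    return n_cells * per_cell_volume_ul


def subtract_blank(absorbance: float, blank: float) -> float:
    """Blank-corrected optical density, floored at zero."""
    return max(0.0, float(absorbance) - float(blank))


def ranking_table(
    dia: pd.DataFrame,
    absorbance: pd.DataFrame | None = None,
    value: str = "positive_count",
    subtract_control: bool = False,
) -> pd.DataFrame:
    """Build a per-(cell_line, lineage) ranking table from replicate tables.

    ``dia`` needs columns cell_line, lineage, condition, timepoint_days and
    the chosen ``value`` column; ``absorbance`` (optional) needs the same
    keys plus ``absorbance`` and optionally ``blank``.  Per line and
    lineage, replicate means per timepoint are summed into Ranking Points;
    ranks are assigned within each lineage (1 = best).  With
    ``subtract_control`` the control-well mean at each timepoint is
    subtracted from the differentiated mean (floored at 0) before summing.
    """
    rows = []
    for (line, lineage), grp in dia.groupby(["cell_line", "lineage"], sort=True):
        pts = _points_from_group(grp, value, subtract_control, ranking_points_dia)
        rows.append({"cell_line": line, "lineage": lineage, "ranking_points_dia": pts})
    table = pd.DataFrame(rows)

    if absorbance is not None and not absorbance.empty:
        ab = absorbance.copy()
        if "blank" in ab.columns:
            ab["absorbance"] = [
                subtract_blank(a, b) for a, b in zip(ab["absorbance"], ab["blank"].fillna(0.0))
            ]
        ab_rows = []
        for (line, lineage), grp in ab.groupby(["cell_line", "lineage"], sort=True):
            pts = _points_from_group(grp, "absorbance", subtract_control, ranking_points_absorbance)
            ab_rows.append({"cell_line": line, "lineage": lineage, "ranking_points_abs": pts})
        table = table.merge(pd.DataFrame(ab_rows), on=["cell_line", "lineage"], how="left")

    for col, rank_col, tied_col in [
        ("ranking_points_dia", "rank_dia", "tied_dia"),
        ("ranking_points_abs", "rank_abs", "tied_abs"),
    ]:
        if col not in table.columns:
            continue
        table[rank_col] = pd.NA
        table[tied_col] = pd.NA
        for lineage, grp in table.groupby("lineage"):
            sub = grp.dropna(subset=[col])
            if sub.empty:
                continue
            ranked = rank_lines(dict(zip(sub["cell_line"], sub[col])))
            for rl in ranked:
                sel = (table["lineage"] == lineage) & (table["cell_line"] == rl.cell_line)
                table.loc[sel, rank_col] = rl.rank
                table.loc[sel, tied_col] = rl.tied
    return table.sort_values(["lineage", "cell_line"], kind="mergesort").reset_index(drop=True)


def _points_from_group(grp: pd.DataFrame, value: str, subtract_control: bool, points_fn) -> float:
    diff = grp[grp["condition"] != "control"] if "condition" in grp.columns else grp
    means = diff.groupby("timepoint_days")[value].mean()
    if subtract_control and "condition" in grp.columns:
        ctrl = grp[grp["condition"] == "control"].groupby("timepoint_days")[value].mean()
        means = (means - ctrl.reindex(means.index).fillna(0.0)).clip(lower=0.0)
    return points_fn(list(means.values))
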