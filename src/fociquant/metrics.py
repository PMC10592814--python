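"""Per-cell colocalization readouts and their plate-level aggregation.

Three readouts are computed from segmented cells and detected foci:

* the Pearson correlation coefficient between two channels over each cell's
  pixels (the colocalization statistic);
* the percentage of cells positive for foci (a cell is positive when its
  foci pixel count exceeds a configurable threshold);
* the percentage of scorable foci positive for a second marker by the
  donut-ratio rule.

Aggregation follows the plate hierarchy: the median over cells gives one
value per image, the median over a well's images gives one value per well,
and the mean and sample standard deviation over a condition's wells give the
condition summary.  Undefined per-cell values (zero-variance cells) are
excluded before medians; unscorable foci are excluded from both numerator
and denominator of positivity percentages and counted separately.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import get_logger
from .model import (
    AnalysisConfig,
    CellLabelMap,
    CellReadout,
    FieldImage,
    FociSet,
    PlateLayout,
    PlateSummary,
)

__all__ = [
    "pearson_per_cell",
    "percent_cells_with_foci",
    "percent_foci_positive",
    "compute_cell_readouts",
    "readouts_frame",
    "foci_frame",
    "aggregate",
]

PixelSet = Union[np.ndarray, tuple[np.ndarray, np.ndarray]]


def _as_index(cell_pixels: PixelSet) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(cell_pixels, tuple):
        return cell_pixels
    mask = np.asarray(cell_pixels)
    if mask.dtype == bool:
        return np.nonzero(mask)
    raise TypeError("cell_pixels must be a boolean mask or (rows, cols) tuple")


def pearson_per_cell(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    cell_pixels: PixelSet,
) -> Optional[float]:
    """Sample Pearson correlation of two channels over one cell's pixels.

    Returns ``None`` when either channel has zero variance over the cell
    (the correlation is undefined there; such cells are excluded from
    aggregation rather than coerced to 0).
    """
    rows, cols = _as_index(cell_pixels)
    if rows.size == 0:
        raise ValueError("cell pixel set is empty")
    x = np.asarray(channel_a, dtype=np.float64)[rows, cols]
    y = np.asarray(channel_b, dtype=np.float64)[rows, cols]
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return None
    return float((dx @ dy) / np.sqrt(sxx * syy))


def percent_cells_with_foci(readouts: Sequence[CellReadout]) -> Optional[float]:
    """100 x (cells with foci) / (cells in group); ``None`` for an empty group."""
    readouts = list(readouts)
    if not readouts:
        return None
    positive = sum(1 for r in readouts if r.has_foci)
    return 100.0 * positive / len(readouts)


def percent_foci_positive(foci: Union[FociSet, Iterable], channel: str) -> Optional[float]:
    """100 x (scorable positive foci) / (scorable foci) for one stain channel.

    Unscorable foci (empty or zero-mean donut) are excluded from numerator
    and denominator; with zero scorable foci the percentage is undefined.
    """
    scorable = [f for f in foci if f.donut_ratio.get(channel) is not None]
    if not scorable:
        return None
    positive = sum(1 for f in scorable if f.positive.get(channel, False))
    return 100.0 * positive / len(scorable)


def _coloc_pair(field: FieldImage, config: AnalysisConfig) -> tuple[str, str]:
    if config.coloc_channels is not None:
        return config.coloc_channels
    if field.n_channels < 2:
        raise ValueError("Pearson correlation needs two channels; field has one")
    pair = (field.channel_names[0], field.channel_names[1])
    get_logger().warning(
        "no colocalization channel pair configured; defaulting to %s", pair
    )
    return pair


def compute_cell_readouts(
    field: FieldImage,
    cells: CellLabelMap,
    foci: FociSet,
    config: AnalysisConfig,
) -> list[CellReadout]:
    """Per-cell Pearson, foci pixel count and foci positivity for one field."""
    name_a, name_b = _coloc_pair(field, config)
    chan_a = field.channel(name_a)
    chan_b = field.channel(name_b)
    foci_pixels: dict[int, int] = {cid: 0 for cid in cells.cell_ids}
    foci_counts: dict[int, int] = {cid: 0 for cid in cells.cell_ids}
    for focus in foci:
        if focus.parent_cell_id in foci_pixels:
            foci_pixels[focus.parent_cell_id] += focus.area
            foci_counts[focus.parent_cell_id] += 1
    readouts = []
    for cid in cells.cell_ids:
        pixels = cells.cell_pixels(cid)
        count = foci_pixels[cid]
        readouts.append(CellReadout(
            well_id=field.well_id,
            field_index=field.field_index,
            cell_id=cid,
            pearson=pearson_per_cell(chan_a, chan_b, pixels),
            foci_pixel_count=count,
            has_foci=count > config.foci_pixel_count_threshold,
            n_foci=foci_counts[cid],
            area=cells.pixel_counts[cid],
            timepoint_min=field.timepoint_min,
        ))
    return readouts


def readouts_frame(readouts: Iterable[CellReadout]) -> pd.DataFrame:
    """Tabulate CellReadout records (one row per cell)."""
    rows = [{
        "well_id": r.well_id,
        "field_index": r.field_index,
        "timepoint_min": r.timepoint_min,
        "cell_id": r.cell_id,
        "area": r.area,
        "pearson": np.nan if r.pearson is None else r.pearson,
        "foci_pixel_count": r.foci_pixel_count,
        "n_foci": r.n_foci,
        "has_foci": r.has_foci,
    } for r in readouts]
    columns = ["well_id", "field_index", "timepoint_min", "cell_id", "area",
               "pearson", "foci_pixel_count", "n_foci", "has_foci"]
    return pd.DataFrame(rows, columns=columns)


def foci_frame(foci: FociSet, well_id: str, field_index: int) -> pd.DataFrame:
    """Tabulate foci (one row per focus per scored stain channel).

    Foci scored in no channel still get one row with a null channel so the
    per-focus geometry is never lost.
    """
    rows = []
    for f in foci:
        base = {
            "well_id": well_id,
            "field_index": field_index,
            "focus_id": f.focus_id,
            "parent_cell_id": np.nan if f.parent_cell_id is None else f.parent_cell_id,
            "area": f.area,
            "circularity": f.circularity,
        }
        if f.donut_ratio:
            for channel, ratio in f.donut_ratio.items():
                rows.append({**base,
                             "channel": channel,
                             "donut_ratio": np.nan if ratio is None else ratio,
                             "scorable": ratio is not None,
                             "positive": f.positive.get(channel, False)})
        else:
            rows.append({**base, "channel": None, "donut_ratio": np.nan,
                         "scorable": False, "positive": False})
    columns = ["well_id", "field_index", "focus_id", "parent_cell_id", "area",
               "circularity", "channel", "donut_ratio", "scorable", "positive"]
    return pd.DataFrame(rows, columns=columns)


def _image_pct_foci(group: pd.DataFrame) -> dict[str, float]:
    out: dict[str, float] = {}
    for channel, sub in group.dropna(subset=["channel"]).groupby("channel"):
        scorable = sub[sub["scorable"]]
        out[f"pct_foci_positive_{channel}"] = (
            np.nan if len(scorable) == 0
            else 100.0 * scorable["positive"].sum() / len(scorable)
        )
        out[f"n_scorable_foci_{channel}"] = int(len(scorable))
        out[f"n_unscorable_foci_{channel}"] = int(len(sub) - len(scorable))
    return out


def aggregate(
    per_cell: pd.DataFrame,
    layout: PlateLayout,
    foci_table: Optional[pd.DataFrame] = None,
) -> PlateSummary:
    """Roll per-cell readouts up the plate hierarchy.

    Per image: median Pearson over that image's cells (undefined cells
    excluded) and the foci-positivity percentages counted over the image.
    Per well: median of the well's per-image values; percentages are
    recounted over the well's pooled cells/foci.  Per condition: mean and
    sample (ddof=1) standard deviation over the condition's wells.
    Time-lapse data aggregates independently per timepoint.
    """
    per_cell = per_cell.copy()
    unknown = sorted(set(per_cell["well_id"]) - set(layout.wells))
    if unknown:
        raise KeyError(f"readouts reference wells absent from layout: {unknown}")
    per_cell["condition"] = [layout.condition_of(w) for w in per_cell["well_id"]]
    front = ["condition", "well_id", "field_index", "timepoint_min"]
    per_cell = per_cell[front + [c for c in per_cell.columns if c not in front]]

    image_keys = ["condition", "well_id", "timepoint_min", "field_index"]
    well_keys = ["condition", "well_id", "timepoint_min"]
    cond_keys = ["condition", "timepoint_min"]

    # ---- per image ----
    image_rows = []
    for keys, group in per_cell.groupby(image_keys, dropna=False, sort=True):
        row = dict(zip(image_keys, keys))
        row["n_cells"] = int(len(group))
        pearson = group["pearson"].dropna()
        row["n_cells_pearson"] = int(len(pearson))
        row["median_pearson"] = float(pearson.median()) if len(pearson) else np.nan
        row["pct_cells_with_foci"] = 100.0 * group["has_foci"].sum() / len(group)
        image_rows.append(row)
    per_image = pd.DataFrame(image_rows)

    pct_cols: list[str] = []
    if foci_table is not None and len(foci_table):
        foci_table = foci_table.copy()
        foci_table["condition"] = [layout.condition_of(w) for w in foci_table["well_id"]]
        img_foci = []
        for keys, group in foci_table.groupby(["condition", "well_id", "field_index"],
                                              dropna=False, sort=True):
            img_foci.append({"condition": keys[0], "well_id": keys[1],
                             "field_index": keys[2], **_image_pct_foci(group)})
        img_foci_df = pd.DataFrame(img_foci)
        per_image = per_image.merge(img_foci_df, how="left",
                                    on=["condition", "well_id", "field_index"])
        pct_cols = sorted(c for c in img_foci_df.columns if c.startswith("pct_foci_positive_"))

    # ---- per well ----
    well_rows = []
    for keys, group in per_image.groupby(well_keys, dropna=False, sort=True):
        row = dict(zip(well_keys, keys))
        row["n_images"] = int(len(group))
        row["n_cells"] = int(group["n_cells"].sum())
        med = group["median_pearson"].dropna()
        row["median_pearson"] = float(med.median()) if len(med) else np.nan
        cells = per_cell[
            (per_cell["well_id"] == row["well_id"])
            & (per_cell["timepoint_min"].isna() if pd.isna(row["timepoint_min"])
               else per_cell["timepoint_min"] == row["timepoint_min"])
        ]
        row["pct_cells_with_foci"] = 100.0 * cells["has_foci"].sum() / len(cells)
        well_rows.append(row)
    per_well = pd.DataFrame(well_rows)

    if foci_table is not None and len(foci_table):
        well_foci = []
        for keys, group in foci_table.groupby(["condition", "well_id"],
                                              dropna=False, sort=True):
            well_foci.append({"condition": keys[0], "well_id": keys[1],
                              **_image_pct_foci(group)})
        per_well = per_well.merge(pd.DataFrame(well_foci), how="left",
                                  on=["condition", "well_id"])

    # ---- per condition ----
    stat_cols = ["median_pearson", "pct_cells_with_foci"] + pct_cols
    cond_rows = []
    for keys, group in per_well.groupby(cond_keys, dropna=False, sort=True):
        row = dict(zip(cond_keys, keys))
        row["n_wells"] = int(len(group))
        row["n_cells"] = int(group["n_cells"].sum())
        for col in stat_cols:
            if col not in group.columns:
                continue
            values = group[col].dropna()
            row[f"{col}_mean"] = float(values.mean()) if len(values) else np.nan
            row[f"{col}_sd"] = (float(values.std(ddof=1)) if len(values) > 1 else np.nan)
        cond_rows.append(row)
    per_condition = pd.DataFrame(cond_rows)

    return PlateSummary(per_cell=per_cell, per_image=per_image,
                        per_well=per_well, per_condition=per_condition)
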