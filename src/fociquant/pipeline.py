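"""End-to-end plate processing: images in, four-level summary tables out.

``run_plate`` discovers field images in a directory (named
``<well>_f<index>.tif``, optionally ``..._t<minutes>`` for time-lapse),
segments cells, detects and scores foci, computes per-cell readouts and
rolls everything up the plate hierarchy.  The run is fully deterministic:
identical inputs and configuration produce byte-identical output tables.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import pandas as pd

from .foci import analyze_foci
from .io import get_logger, read_field, write_tables
from .metrics import aggregate, compute_cell_readouts, foci_frame, readouts_frame
from .model import AnalysisConfig, PlateLayout, PlateSummary
from .segmentation import segment_field

__all__ = ["discover_fields", "process_field", "run_plate"]

_FIELD_RE = re.compile(
    r"^(?P<well>[A-H]\d{2})_f(?P<field>\d+)(?:_t(?P<tp>\d+))?\.(?:tif|tiff|ome\.tif)$",
    re.IGNORECASE,
)


def discover_fields(input_dir) -> list[dict]:
    """Find plate field images and parse well/field/timepoint from filenames."""
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {input_dir}")
    entries = []
    for path in sorted(input_dir.iterdir()):
        match = _FIELD_RE.match(path.name)
        if match:
            entries.append({
                "path": path,
                "well_id": match["well"].upper(),
                "field_index": int(match["field"]),
                "timepoint_min": float(match["tp"]) if match["tp"] else None,
            })
    if not entries:
        raise FileNotFoundError(
            f"no field images matching '<well>_f<index>.tif' in {input_dir}"
        )
    return entries


def process_field(field, config: AnalysisConfig):
    """Segment one field, analyze its foci, and compute per-cell readouts."""
    cells = segment_field(field, config)
    foci = analyze_foci(field, cells, config)
    readouts = compute_cell_readouts(field, cells, foci, config)
    return cells, foci, readouts


def run_plate(
    input_dir,
    config: AnalysisConfig,
    layout: PlateLayout,
    out_dir=None,
    channel_names: Optional[list[str]] = None,
) -> PlateSummary:
    """Process every field image of a plate and aggregate the readouts.

    ``channel_names`` labels the planes of each TIFF in order; it defaults
    to the configured segmentation channel plus stain channels when the
    files are two-plane stacks.
    """
    logger = get_logger()
    if channel_names is None:
        extras = [c for c in config.stain_channels if c != config.segmentation_channel]
        channel_names = [config.segmentation_channel] + extras
    entries = discover_fields(input_dir)

    all_readouts = []
    foci_frames = []
    for entry in entries:
        field = read_field(
            entry["path"], channel_names,
            well_id=entry["well_id"], field_index=entry["field_index"],
            timepoint_min=entry["timepoint_min"],
        )
        logger.info("stage=segment well=%s field=%d", field.well_id, field.field_index)
        cells, foci, readouts = process_field(field, config)
        logger.info(
            "stage=foci well=%s field=%d cells=%d foci=%d",
            field.well_id, field.field_index, cells.n_cells, len(foci),
        )
        all_readouts.extend(readouts)
        foci_frames.append(foci_frame(foci, field.well_id, field.field_index))

    per_cell = readouts_frame(all_readouts)
    foci_frames = [f for f in foci_frames if len(f)]
    foci_table = (pd.concat(foci_frames, ignore_index=True)
                  if foci_frames else pd.DataFrame())
    summary = aggregate(per_cell, layout, foci_table if len(foci_table) else None)
    if out_dir is not None:
        out_dir = Path(out_dir)
        paths = write_tables(summary, out_dir)
        if len(foci_table):
            foci_path = out_dir / "foci.csv"
            foci_table.to_csv(foci_path, index=False, lineterminator="\n")
            paths.append(foci_path)
        logger.info("stage=write tables=%d dir=%s", len(paths), out_dir)
    return summary
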