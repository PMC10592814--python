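"""Reading images, writing result tables, and loading run configuration.

Images are plain or OME TIFF, single- or multi-plane; intensities are
preserved bit-exactly on a write/read round trip of uncompressed files.
Result tables are UTF-8 CSV with a header row.  Configuration (plate layout
plus analysis parameters) lives in one human-editable YAML file.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import AnalysisConfig, FieldImage, PlateLayout, PlateSummary

__all__ = [
    "read_field",
    "write_field",
    "write_tables",
    "read_tables",
    "load_run_config",
    "save_run_config",
    "get_logger",
]

_TABLE_FILES = {
    "per_cell": "per_cell.csv",
    "per_image": "per_image.csv",
    "per_well": "per_well.csv",
    "per_condition": "per_condition.csv",
}


def get_logger(name: str = "fociquant") -> logging.Logger:
    """Package logger with structured ``timestamp | stage | message`` lines."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s | %(name)s | %(levelname)s | %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


def read_field(
    path,
    channel_names: list[str],
    well_id: str = "",
    field_index: int = 0,
    timepoint_min: Optional[float] = None,
    pixel_size_um: Optional[float] = None,
) -> FieldImage:
    """Read one TIFF field of view and label its planes.

    A single-plane grayscale file yields one channel; a multi-plane stack is
    matched to ``channel_names`` in plane order.  Intensities are converted
    to float64 without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile error text varies
        raise ValueError(f"could not read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected 2-D planes or a plane stack, got shape {data.shape}"
        )
    if data.shape[0] != len(channel_names):
        raise ValueError(
            f"{path}: plane/channel mismatch — file has {data.shape[0]} plane(s) "
            f"but {len(channel_names)} channel name(s) {list(channel_names)}"
        )
    return FieldImage(
        pixels=data,
        channel_names=list(channel_names),
        well_id=well_id,
        field_index=field_index,
        timepoint_min=timepoint_min,
        pixel_size_um=pixel_size_um,
    )


def write_field(field: FieldImage, path, dtype=np.float32) -> Path:
    """Write a FieldImage as an uncompressed multi-plane TIFF.

    ``dtype`` controls the stored sample format; pass an integer dtype for
    bit-exact round trips of integer-valued data.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = field.pixels
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        if data.min() < info.min or data.max() > info.max:
            raise ValueError(
                f"intensities outside {np.dtype(dtype).name} range; cannot write {path}"
            )
        data = np.round(data).astype(dtype)
    else:
        data = data.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def write_tables(summary: PlateSummary, out_dir) -> list[Path]:
    """Write the four aggregation levels as CSV files with stable columns.

    Values are written at full float precision so that re-reading reproduces
    them exactly; repeated runs on identical inputs are byte-identical.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    paths: list[Path] = []
    for level, fname in _TABLE_FILES.items():
        frame = getattr(summary, level)
        target = out_dir / fname
        frame.to_csv(target, index=False, lineterminator="\n")
        paths.append(target)
    return paths


def read_tables(out_dir) -> PlateSummary:
    """Read back tables previously written by :func:`write_tables`."""
    out_dir = Path(out_dir)
    frames = {}
    for level, fname in _TABLE_FILES.items():
        path = out_dir / fname
        if not path.exists():
            raise FileNotFoundError(f"missing summary table {path}")
        frames[level] = pd.read_csv(path)
    return PlateSummary(**frames)


def load_run_config(path) -> tuple[AnalysisConfig, Optional[PlateLayout]]:
    """Load an analysis config and (optionally) a plate layout from one YAML file.

    Layout:

    .. code-block:: yaml

        analysis:
          segmentation_channel: LC3B
          donut_threshold: 1.75
        layout:
          B02: {condition: untreated, replicate: r1}
          B03: cGAMP            # shorthand: condition only
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level of config must be a mapping")
    config = AnalysisConfig.from_dict(data.get("analysis", {}) or {})
    layout = None
    if data.get("layout"):
        layout = PlateLayout.from_mapping(data["layout"])
    return config, layout


def save_run_config(config: AnalysisConfig, path, layout: Optional[PlateLayout] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: dict = {"analysis": config.to_dict()}
    if layout is not None:
        payload["layout"] = {w: dict(info) for w, info in layout.wells.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path
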