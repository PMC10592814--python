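"""Shared data model for plate-based fluorescence image quantification.

Conventions used throughout the package:

* pixel indices are row-major, 0-based, and always ordered ``(row, column)``;
* image stacks are indexed ``(channel, row, column)``;
* intensities are converted to ``float64`` once, at read time, and are never
  rescaled or clipped by container construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FieldImage",
    "PlateLayout",
    "AnalysisConfig",
    "CellLabelMap",
    "Focus",
    "FociSet",
    "CellReadout",
    "PlateSummary",
    "CtTable",
    "IntensityTable",
    "FoldChangeTable",
]


@dataclass
class FieldImage:
    """One multi-channel 2-D field of view.

    Parameters
    ----------
    pixels
        3-D array indexed ``(channel, row, column)`` of non-negative, finite
        intensities in arbitrary detector units.
    channel_names
        Ordered channel labels, one per plane (e.g. ``["LC3B", "Ub"]``).
    well_id
        Plate well identifier, e.g. ``"B07"``.
    field_index
        0-based index of the field within its well.
    timepoint_min
        Acquisition time in minutes for time-lapse series, else ``None``.
    pixel_size_um
        Physical pixel size in micrometres, if known.
    """

    pixels: np.ndarray
    channel_names: list[str]
    well_id: str = ""
    field_index: int = 0
    timepoint_min: Optional[float] = None
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError(
                f"pixels must be (channel, row, column); got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.pixels.min(initial=0.0) < 0:
            raise ValueError("pixels contain negative intensities")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError(
                f"plane/channel mismatch: {self.pixels.shape[0]} planes but "
                f"{len(self.channel_names)} channel names {self.channel_names}"
            )
        if self.field_index < 0:
            raise ValueError("field_index must be >= 0")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, columns) of every plane."""
        return self.pixels.shape[1], self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D plane for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.pixels[idx]


@dataclass
class PlateLayout:
    """Maps each well to its experimental condition and replicate group."""

    wells: dict[str, dict]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "PlateLayout":
        wells: dict[str, dict] = {}
        for well_id, entry in mapping.items():
            if isinstance(entry, str):
                wells[well_id] = {"condition": entry, "replicate": well_id}
            else:
                info = dict(entry)  # type: ignore[arg-type]
                if "condition" not in info:
                    raise ValueError(f"well {well_id!r} layout entry lacks a condition")
                info.setdefault("replicate", well_id)
                wells[well_id] = info
        return cls(wells=wells)

    def condition_of(self, well_id: str) -> str:
        if well_id not in self.wells:
            raise KeyError(f"well {well_id!r} not present in plate layout")
        return str(self.wells[well_id]["condition"])

    def replicate_of(self, well_id: str) -> str:
        if well_id not in self.wells:
            raise KeyError(f"well {well_id!r} not present in plate layout")
        return str(self.wells[well_id]["replicate"])

    @property
    def well_ids(self) -> list[str]:
        return sorted(self.wells)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for well_id in self.well_ids:
            cond = self.condition_of(well_id)
            if cond not in seen:
                seen.append(cond)
        return seen


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    Scale parameters are in pixels.  Derived defaults follow the configured
    cell radius: background estimation scale is 4x the radius, the watershed
    blur sigma is half the radius, and the equalization sigma is a third of
    the radius — between the focus and the cell scale, so compact spots
    stand out while the cell interior flattens to ~1.  Thresholds left as
    ``None`` are chosen automatically (Otsu) per image.
    """

    segmentation_channel: str = "LC3B"
    foci_channel: str = "LC3B"
    coloc_channels: Optional[tuple[str, str]] = None
    stain_channels: tuple[str, ...] = ()

    cell_radius_px: float = 12.0
    background_scale: Optional[float] = None
    blur_sigma: Optional[float] = None
    equalize_sigma: Optional[float] = None

    cell_intensity_threshold: Optional[float] = None
    cell_size_bounds: tuple[int, int] = (80, 20000)

    foci_raw_threshold: Optional[float] = None
    eq_threshold: float = 1.5
    foci_size_bounds: tuple[int, int] = (3, 50)
    circularity_threshold: float = 0.5
    circularity_channels: tuple[str, ...] = ()

    foci_pixel_count_threshold: int = 5
    donut_radius: int = 2
    donut_threshold: float = 1.75

    exclude_border_cells: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_radius_px <= 0:
            raise ValueError("cell_radius_px must be positive")
        for name in ("background_scale", "blur_sigma", "equalize_sigma"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.circularity_threshold <= 1:
            raise ValueError("circularity_threshold must lie in (0, 1]")
        if self.donut_radius <= 0:
            raise ValueError("donut_radius must be a positive integer")
        if self.donut_threshold <= 0:
            raise ValueError("donut_threshold must be positive")
        for name in ("cell_size_bounds", "foci_size_bounds"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")
        if self.foci_pixel_count_threshold < 0:
            raise ValueError("foci_pixel_count_threshold must be >= 0")

    # -- derived defaults ---------------------------------------------------
    @property
    def effective_background_scale(self) -> float:
        return self.background_scale if self.background_scale is not None else 4.0 * self.cell_radius_px

    @property
    def effective_blur_sigma(self) -> float:
        return self.blur_sigma if self.blur_sigma is not None else 0.5 * self.cell_radius_px

    @property
    def effective_equalize_sigma(self) -> float:
        return self.equalize_sigma if self.equalize_sigma is not None else self.cell_radius_px / 3.0

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "AnalysisConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("coloc_channels", "stain_channels", "circularity_channels",
                    "cell_size_bounds", "foci_size_bounds"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])  # type: ignore[arg-type]
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        out: dict = {}
        for name in self.__dataclass_fields__:  # type: ignore[attr-defined]
            value = getattr(self, name)
            if isinstance(value, tuple):
                value = list(value)
            out[name] = value
        return out


@dataclass
class CellLabelMap:
    """Integer label image: 0 = background, k >= 1 = pixels of cell k."""

    labels: np.ndarray
    cell_ids: list[int] = field(default_factory=list)
    pixel_counts: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "CellLabelMap":
        labels = np.asarray(labels)
        if labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        return cls(
            labels=labels.astype(np.int32),
            cell_ids=[int(i) for i in ids],
            pixel_counts={int(i): int(c) for i, c in zip(ids, counts)},
        )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_pixels(self, cell_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) index arrays of one cell's pixels."""
        if cell_id not in self.pixel_counts:
            raise KeyError(f"no cell with label {cell_id}")
        return np.nonzero(self.labels == cell_id)


@dataclass
class Focus:
    """One detected punctum: a connected component of the foci mask."""

    focus_id: int
    rows: np.ndarray
    cols: np.ndarray
    area: int
    circularity: float
    parent_cell_id: Optional[int] = None
    donut_ratio: dict[str, Optional[float]] = field(default_factory=dict)
    positive: dict[str, bool] = field(default_factory=dict)

    def scorable(self, channel: str) -> bool:
        """True if a donut ratio was computed (donut non-empty, mean > 0)."""
        return self.donut_ratio.get(channel) is not None


@dataclass
class FociSet:
    """All foci detected in one field, with the mask geometry they share."""

    foci: list[Focus]
    shape: tuple[int, int]
    channel: str = ""

    def __len__(self) -> int:
        return len(self.foci)

    def __iter__(self):
        return iter(self.foci)

    def mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for f in self.foci:
            out[f.rows, f.cols] = True
        return out

    def label_image(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.int32)
        for f in self.foci:
            out[f.rows, f.cols] = f.focus_id
        return out


@dataclass
class CellReadout:
    """Per-cell measurements feeding the plate-level aggregation."""

    well_id: str
    field_index: int
    cell_id: int
    pearson: Optional[float]
    foci_pixel_count: int
    has_foci: bool
    n_foci: int = 0
    area: int = 0
    timepoint_min: Optional[float] = None


@dataclass
class PlateSummary:
    """Hierarchical statistics: per-cell -> per-image -> per-well -> per-condition."""

    per_cell: pd.DataFrame
    per_image: pd.DataFrame
    per_well: pd.DataFrame
    per_condition: pd.DataFrame

    LEVELS = ("per_cell", "per_image", "per_well", "per_condition")

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in self.LEVELS}


class CtTable:
    """qPCR Ct values with a designated reference gene and baseline condition.

    The underlying frame has columns ``sample_id, condition, replicate, gene,
    ct``.  Every (sample_id, gene) pair must be unique and the reference gene
    must be measured for every sample.
    """

    REQUIRED = ("sample_id", "condition", "replicate", "gene", "ct")

    def __init__(self, frame: pd.DataFrame, reference_gene: str = "ACTB",
                 baseline_condition: str = "untreated"):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"Ct table lacks required columns: {missing}")
        frame = frame.loc[:, list(self.REQUIRED)].copy()
        frame["ct"] = frame["ct"].astype(float)
        dup = frame.duplicated(subset=["sample_id", "gene"])
        if dup.any():
            raise ValueError("duplicate (sample_id, gene) rows in Ct table")
        samples = set(frame["sample_id"])
        with_ref = set(frame.loc[frame["gene"] == reference_gene, "sample_id"])
        lacking = sorted(samples - with_ref)
        if lacking:
            raise ValueError(
                f"reference gene {reference_gene!r} missing for samples {lacking}"
            )
        if baseline_condition not in set(frame["condition"]):
            raise ValueError(f"baseline condition {baseline_condition!r} absent from table")
        self.frame = frame
        self.reference_gene = reference_gene
        self.baseline_condition = baseline_condition


class IntensityTable:
    """Immunoblot band/lane volumes with loading controls.

    Columns: ``lane_id, condition, target_band_volume, loading_control_volume``.
    Loading-control volumes must be strictly positive.
    """

    REQUIRED = ("lane_id", "condition", "target_band_volume", "loading_control_volume")

    def __init__(self, frame: pd.DataFrame, reference_condition: str = "untreated"):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"intensity table lacks required columns: {missing}")
        frame = frame.loc[:, list(self.REQUIRED)].copy()
        for col in ("target_band_volume", "loading_control_volume"):
            frame[col] = frame[col].astype(float)
        if (frame["target_band_volume"] < 0).any():
            raise ValueError("target band volumes must be non-negative")
        if (frame["loading_control_volume"] <= 0).any():
            raise ValueError("loading-control volumes must be strictly positive")
        if reference_condition not in set(frame["condition"]):
            raise ValueError(f"reference condition {reference_condition!r} absent from table")
        self.frame = frame
        self.reference_condition = reference_condition


@dataclass
class FoldChangeTable:
    """Normalized values, fold changes vs baseline, and per-condition summaries."""

    per_sample: pd.DataFrame
    per_condition: pd.DataFrame
    baseline_condition: str
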