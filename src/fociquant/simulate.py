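"""Synthetic two-channel fluorescence fields with known ground truth.

Each scene emulates one spinning-disk field of view: rounded cells on an
uneven background, each cell carrying zero or more small bright perinuclear
foci.  Channel A (the segmentation/foci channel, e.g. an LC3B fusion)
receives every focus; channel B (the immunostain channel) receives a matched
spot only for foci drawn as colocalized, with probability ``p``.  The
diffuse intracellular signal of the two channels is built from a shared and
an independent smoothed-noise component mixed to achieve a target per-cell
Pearson correlation ``rho``:

    A_texture = S,    B_texture = rho * S + sqrt(1 - rho^2) * I

with S, I independent unit-variance smoothed fields, so the pixel-wise
correlation of the noiseless textures is ``rho``.  Poisson shot noise is
applied to the noiseless expectation, then Gaussian read noise is added;
both are optional.  Everything is deterministic under the scene seed, and
plates derive one child seed per (well, field) from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .io import write_field
from .model import FieldImage, PlateLayout

__all__ = ["SceneSpec", "GroundTruth", "generate_scene", "generate_plate",
           "generate_ct_table"]

_PLACEMENT_RETRIES = 200  # attempts per cell before packing is declared infeasible


@dataclass
class SceneSpec:
    """Parameters of one synthetic field of view.

    Intensity units are arbitrary detector counts chosen so that shot noise
    at the cell base intensity is small relative to the diffuse texture.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 12
    cell_radius_mean: float = 12.0
    cell_radius_sd: float = 1.5
    touching_pairs: bool = False
    dome_profile: bool = False          # Gaussian-intensity cells (bright center)

    foci_fraction: float = 1.0          # f: fraction of cells bearing foci
    foci_per_cell_mean: float = 3.0     # Poisson mean, zero-truncated for bearers
    focus_radius_px: float = 2.0        # spot Gaussian s.d. = radius / 2
    focus_amplitude: float = 900.0      # channel-A spot peak amplitude
    stain_amplitude: float = 900.0      # channel-B spot peak amplitude (if colocalized)
    coloc_fraction: float = 1.0         # p: probability a focus is matched in B
    perinuclear: bool = True

    rho: float = 0.0                    # target diffuse per-cell correlation
    cell_base_intensity: float = 300.0
    cell_texture_sd: float = 60.0
    texture_smooth_sigma: float = 2.0

    background_level: float = 20.0
    background_gradient: float = 30.0   # linear ramp amplitude across the field
    read_noise_sd: float = 2.0
    shot_noise: bool = True

    channel_names: tuple[str, str] = ("LC3B", "Ub")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.foci_fraction <= 1:
            raise ValueError("foci_fraction must lie in [0, 1]")
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must lie in [-1, 1]")
        for name in ("cell_radius_mean", "focus_radius_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cell_radius_sd", "foci_per_cell_mean", "focus_amplitude",
                     "stain_amplitude", "cell_base_intensity", "cell_texture_sd",
                     "background_level", "background_gradient", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery tests."""

    cell_labels: np.ndarray
    cells: pd.DataFrame     # cell_id, row, col, radius, has_foci, n_foci
    foci: pd.DataFrame      # focus_id, cell_id, row, col, colocalized
    foci_fraction: float
    coloc_fraction: float
    rho: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _truncated_poisson(rng: np.random.Generator, mean: float) -> int:
    """Zero-truncated Poisson draw by CDF inversion.

    ``mean <= 0`` degenerates to exactly 1, so scenes can be generated with
    exactly one focus per bearing cell.
    """
    if mean <= 0:
        return 1
    p0 = float(np.exp(-mean))
    u = rng.uniform(p0, 1.0)
    return max(1, int(stats.poisson.ppf(u, mean)))


def _place_cells(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping cell centers (or touching pairs)."""
    rows, cols = spec.shape
    centers: list[tuple[float, float, float]] = []  # row, col, radius
    margin_gap = 3.0

    def fits(r0: float, c0: float, rad: float, against=None) -> bool:
        if not (rad + 2 <= r0 <= rows - rad - 2 and rad + 2 <= c0 <= cols - rad - 2):
            return False
        others = centers if against is None else against
        return all((r0 - rr) ** 2 + (c0 - cc) ** 2 >= (rad + rr2 + margin_gap) ** 2
                   for rr, cc, rr2 in others)

    def draw_radius() -> float:
        return max(3.0, rng.normal(spec.cell_radius_mean, spec.cell_radius_sd))

    n_target = spec.n_cells
    if spec.touching_pairs and n_target % 2:
        raise ValueError("touching_pairs scenes need an even n_cells")

    if spec.touching_pairs:
        for _ in range(n_target // 2):
            placed = False
            existing = list(centers)
            for _ in range(_PLACEMENT_RETRIES):
                r1, r2 = draw_radius(), draw_radius()
                sep = 0.9 * (r1 + r2)  # overlap by a thin neck
                theta = rng.uniform(0, 2 * np.pi)
                rc = rng.uniform(0, rows), rng.uniform(0, cols)
                p1 = (rc[0] - 0.5 * sep * np.sin(theta), rc[1] - 0.5 * sep * np.cos(theta))
                p2 = (rc[0] + 0.5 * sep * np.sin(theta), rc[1] + 0.5 * sep * np.cos(theta))
                # each member must clear the border and all *other* pairs,
                # but not its own partner (they overlap by construction)
                if fits(*p1, r1, against=existing) and fits(*p2, r2, against=existing):
                    centers.append((p1[0], p1[1], r1))
                    centers.append((p2[0], p2[1], r2))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"infeasible packing: could not place pair after "
                    f"{_PLACEMENT_RETRIES} attempts (n_cells={n_target}, "
                    f"shape={spec.shape})"
                )
    else:
        for _ in range(n_target):
            for _ in range(_PLACEMENT_RETRIES):
                rad = draw_radius()
                r0 = rng.uniform(rad + 2, rows - rad - 2)
                c0 = rng.uniform(rad + 2, cols - rad - 2)
                if fits(r0, c0, rad):
                    centers.append((r0, c0, rad))
                    break
            else:
                raise ValueError(
                    f"infeasible packing: could not place cell "
                    f"{len(centers) + 1}/{n_target} after {_PLACEMENT_RETRIES} "
                    f"attempts (shape={spec.shape})"
                )
    return centers


def _paint_labels(shape, centers, dome_profile: bool = False):
    """Label map assigning overlap pixels to the nearest center (scaled by radius).

    Returns ``(labels, profile)``: the per-pixel intensity profile factor is
    1 inside cells for flat cells, or a Gaussian dome (bright center, s.d.
    half the radius) when ``dome_profile`` is set.
    """
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    profile = np.zeros(shape, dtype=np.float64)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for idx, (r0, c0, rad) in enumerate(centers, start=1):
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        norm = d2 / rad**2
        inside = (d2 <= rad**2) & (norm < best)
        labels[inside] = idx
        best = np.where(inside, norm, best)
        if dome_profile:
            profile[inside] = np.exp(-0.5 * norm[inside] / 0.45**2)
        else:
            profile[inside] = 1.0
    return labels, profile


def _smooth_unit_field(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    raw = rng.standard_normal(shape)
    smooth = ndi.gaussian_filter(raw, sigma, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _add_spot(image: np.ndarray, r0: float, c0: float, amplitude: float, sd: float) -> None:
    rows, cols = image.shape
    half = int(np.ceil(4 * sd))
    r_lo, r_hi = max(0, int(r0) - half), min(rows, int(r0) + half + 1)
    c_lo, c_hi = max(0, int(c0) - half), min(cols, int(c0) + half + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    image[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sd**2)
    )


def _draw_focus_position(rng, r0, c0, rad, perinuclear: bool):
    if perinuclear:
        theta = rng.uniform(0, 2 * np.pi)
        pole = (r0 + 0.5 * rad * np.sin(theta), c0 + 0.5 * rad * np.cos(theta))
        for _ in range(50):
            fr = rng.normal(pole[0], rad / 3.0)
            fc = rng.normal(pole[1], rad / 3.0)
            if (fr - r0) ** 2 + (fc - c0) ** 2 <= (0.8 * rad) ** 2:
                return fr, fc
        return pole
    while True:
        fr = rng.uniform(r0 - 0.8 * rad, r0 + 0.8 * rad)
        fc = rng.uniform(c0 - 0.8 * rad, c0 + 0.8 * rad)
        if (fr - r0) ** 2 + (fc - c0) ** 2 <= (0.8 * rad) ** 2:
            return fr, fc


def generate_scene(
    spec: SceneSpec,
    rng: Optional[np.random.Generator] = None,
    well_id: str = "A01",
    field_index: int = 0,
    timepoint_min: Optional[float] = None,
) -> tuple[FieldImage, GroundTruth]:
    """Draw one synthetic field of view and its ground truth."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    centers = _place_cells(spec, rng)
    labels, profile = _paint_labels(spec.shape, centers, spec.dome_profile)
    cell_region = labels > 0

    shared = _smooth_unit_field(spec.shape, spec.texture_smooth_sigma, rng)
    indep = _smooth_unit_field(spec.shape, spec.texture_smooth_sigma, rng)
    mix = spec.rho * shared + np.sqrt(max(0.0, 1 - spec.rho**2)) * indep

    ramp = np.linspace(0.0, 1.0, cols)[None, :] * np.ones((rows, 1))
    background = spec.background_level + spec.background_gradient * ramp

    chan_a = background.copy()
    chan_b = background.copy()
    base = spec.cell_base_intensity * profile[cell_region]
    chan_a[cell_region] += base + spec.cell_texture_sd * shared[cell_region]
    chan_b[cell_region] += base + spec.cell_texture_sd * mix[cell_region]

    # f and p are realized as exact per-scene fractions (quota assignment),
    # so the drawn ground truth matches the requested fractions and recovery
    # errors measure the pipeline, not generator sampling noise
    n = len(centers)
    n_bearing = int(round(spec.foci_fraction * n))
    bearing_ids = set(rng.permutation(n)[:n_bearing] + 1) if n else set()

    cell_rows, foci_rows = [], []
    spot_sd = spec.focus_radius_px / 2.0
    focus_id = 0
    for cell_id, (r0, c0, rad) in enumerate(centers, start=1):
        bearing = cell_id in bearing_ids
        n_foci = _truncated_poisson(rng, spec.foci_per_cell_mean) if bearing else 0
        for _ in range(n_foci):
            fr, fc = _draw_focus_position(rng, r0, c0, rad, spec.perinuclear)
            _add_spot(chan_a, fr, fc, spec.focus_amplitude, spot_sd)
            focus_id += 1
            foci_rows.append({"focus_id": focus_id, "cell_id": cell_id,
                              "row": fr, "col": fc, "radius": spec.focus_radius_px,
                              "colocalized": False})
        cell_rows.append({"cell_id": cell_id, "row": r0, "col": c0, "radius": rad,
                          "has_foci": bearing, "n_foci": n_foci})

    n_coloc = int(round(spec.coloc_fraction * len(foci_rows)))
    for idx in rng.permutation(len(foci_rows))[:n_coloc]:
        row = foci_rows[int(idx)]
        row["colocalized"] = True
        _add_spot(chan_b, row["row"], row["col"], spec.stain_amplitude, spot_sd)

    chan_a = np.clip(chan_a, 0.0, None)
    chan_b = np.clip(chan_b, 0.0, None)
    if spec.shot_noise:
        chan_a = rng.poisson(chan_a).astype(np.float64)
        chan_b = rng.poisson(chan_b).astype(np.float64)
    if spec.read_noise_sd > 0:
        chan_a = chan_a + rng.normal(0.0, spec.read_noise_sd, spec.shape)
        chan_b = chan_b + rng.normal(0.0, spec.read_noise_sd, spec.shape)
    chan_a = np.clip(chan_a, 0.0, None)
    chan_b = np.clip(chan_b, 0.0, None)

    image = FieldImage(
        pixels=np.stack([chan_a, chan_b]),
        channel_names=list(spec.channel_names),
        well_id=well_id,
        field_index=field_index,
        timepoint_min=timepoint_min,
    )
    cells_df = pd.DataFrame(cell_rows, columns=["cell_id", "row", "col", "radius",
                                                "has_foci", "n_foci"])
    foci_df = pd.DataFrame(foci_rows, columns=["focus_id", "cell_id", "row", "col",
                                               "radius", "colocalized"])
    truth = GroundTruth(cell_labels=labels, cells=cells_df, foci=foci_df,
                        foci_fraction=spec.foci_fraction,
                        coloc_fraction=spec.coloc_fraction, rho=spec.rho)
    return image, truth


def field_seed(master_seed: int, well_index: int, field_index: int) -> np.random.Generator:
    """Deterministic per-(well, field) generator derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(well_index), int(field_index)])
    return np.random.default_rng(ss)


def generate_plate(
    layout: PlateLayout,
    scene_specs: Mapping[str, SceneSpec],
    fields_per_well: int = 3,
    seed: int = 0,
    out_dir=None,
) -> tuple[list[tuple[FieldImage, GroundTruth]], Optional[Path]]:
    """Generate every field of a plate, optionally writing it to disk.

    Per-field seeds derive deterministically from the master seed and the
    well/field position, so the same master seed reproduces the plate
    byte-for-byte.  When ``out_dir`` is given, images are written as 16-bit
    TIFF named ``<well>_f<field>.tif`` and ground truth as CSV tables under
    ``out_dir/ground_truth/``.
    """
    missing = sorted({layout.condition_of(w) for w in layout.well_ids} - set(scene_specs))
    if missing:
        raise KeyError(f"no SceneSpec for conditions: {missing}")
    results: list[tuple[FieldImage, GroundTruth]] = []
    cell_tables, foci_tables = [], []
    for well_index, well_id in enumerate(layout.well_ids):
        spec = scene_specs[layout.condition_of(well_id)]
        for fidx in range(fields_per_well):
            rng = field_seed(seed, well_index, fidx)
            image, truth = generate_scene(spec, rng=rng, well_id=well_id,
                                          field_index=fidx)
            results.append((image, truth))
            cells = truth.cells.copy()
            cells.insert(0, "field_index", fidx)
            cells.insert(0, "well_id", well_id)
            cell_tables.append(cells)
            foci = truth.foci.copy()
            foci.insert(0, "field_index", fidx)
            foci.insert(0, "well_id", well_id)
            foci_tables.append(foci)

    written = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        gt_dir = out_dir / "ground_truth"
        gt_dir.mkdir(parents=True, exist_ok=True)
        for image, _ in results:
            write_field(image, out_dir / f"{image.well_id}_f{image.field_index}.tif",
                        dtype=np.uint16)
        def _concat(tables):
            tables = [t for t in tables if len(t)] or tables[:1]
            return pd.concat(tables, ignore_index=True)

        _concat(cell_tables).to_csv(gt_dir / "cells.csv", index=False,
                                    lineterminator="\n")
        _concat(foci_tables).to_csv(gt_dir / "foci.csv", index=False,
                                    lineterminator="\n")
        cond_rows = [{"condition": cond,
                      "foci_fraction": scene_specs[cond].foci_fraction,
                      "coloc_fraction": scene_specs[cond].coloc_fraction,
                      "rho": scene_specs[cond].rho}
                     for cond in sorted(scene_specs)]
        pd.DataFrame(cond_rows).to_csv(gt_dir / "conditions.csv", index=False,
                                       lineterminator="\n")
        written = out_dir
    return results, written


def generate_ct_table(
    true_folds: Mapping[str, Mapping[str, float]],
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    baseline_condition: str = "untreated",
    reference_gene: str = "ACTB",
    reference_ct: float = 20.0,
    baseline_delta_ct: float = 7.0,
) -> "CtTable":
    """Simulate a qPCR Ct table with known per-condition fold changes.

    ``true_folds`` maps condition -> gene -> fold change relative to the
    baseline condition (the baseline itself is implied at fold 1 and need
    not be listed).  The reference-gene Ct is drawn around ``reference_ct``;
    each target Ct is the sample's reference Ct plus the baseline dCt minus
    log2(fold), plus Gaussian noise of s.d. ``ct_noise_sd``.
    """
    from .model import CtTable

    rng = np.random.default_rng(seed)
    genes = sorted({g for folds in true_folds.values() for g in folds})
    if not genes:
        raise ValueError("true_folds names no genes")
    conditions = sorted(set(true_folds) | {baseline_condition})
    for cond in conditions:
        for gene in genes:
            fold = true_folds.get(cond, {}).get(gene, 1.0)
            if fold <= 0:
                raise ValueError(f"fold for {cond}/{gene} must be positive")
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sample_id = f"{cond}_r{rep}"
            ref_ct = reference_ct + rng.normal(0.0, ct_noise_sd)
            rows.append({"sample_id": sample_id, "condition": cond,
                         "replicate": f"r{rep}", "gene": reference_gene,
                         "ct": ref_ct})
            for gene in genes:
                fold = true_folds.get(cond, {}).get(gene, 1.0)
                ct = (ref_ct + baseline_delta_ct - np.log2(fold)
                      + rng.normal(0.0, ct_noise_sd))
                rows.append({"sample_id": sample_id, "condition": cond,
                             "replicate": f"r{rep}", "gene": gene, "ct": ct})
    frame = pd.DataFrame(rows)
    return CtTable(frame, reference_gene=reference_gene,
                   baseline_condition=baseline_condition)
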