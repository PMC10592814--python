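"""Punctate foci detection and ring ("donut") positivity scoring.

Foci are found by equalizing the channel — dividing it by its own Gaussian
blur so slow background flattens to ~1 while compact bright spots stand out —
and keeping pixels bright in *both* the raw and the equalized image.  The
surviving connected components are filtered by size and optionally by
circularity.  Each focus is then scored for a second marker by the ratio of
its mean stain intensity to the mean in a surrounding dilated ring that
excludes every focus pixel; a ratio strictly above the positivity threshold
(default 1.75) calls the focus positive.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .model import AnalysisConfig, CellLabelMap, FieldImage, Focus, FociSet

__all__ = [
    "equalize",
    "detect_foci",
    "donut_ratio",
    "classify_positive",
    "score_foci",
    "assign_parents",
    "analyze_foci",
]


def equalize(image: np.ndarray, sigma: float, epsilon: Optional[float] = None) -> np.ndarray:
    """Divide an image by its own Gaussian blur.

    Flat regions map to ~1; spots much smaller than ``sigma`` map to values
    above 1.  ``epsilon`` regularizes the division in dark regions; it
    defaults to ``1e-6 * mean(image)`` (or 1e-6 for an all-zero image).
    """
    if sigma <= 0:
        raise ValueError("equalization sigma must be positive")
    image = np.asarray(image, dtype=np.float64)
    if epsilon is None:
        mean = float(image.mean()) if image.size else 0.0
        epsilon = 1e-6 * mean if mean > 0 else 1e-6
    blurred = ndi.gaussian_filter(image, sigma=sigma, mode="nearest")
    return image / (blurred + epsilon)


def _circularity(region) -> float:
    """4*pi*area / perimeter^2, clipped into (0, 1] for tiny components."""
    perimeter = region.perimeter
    if perimeter <= 0:
        return 1.0
    return float(min(1.0, 4.0 * math.pi * region.area / perimeter**2))


def detect_foci(
    image: np.ndarray,
    equalized: np.ndarray,
    raw_threshold: float,
    eq_threshold: float,
    size_bounds: tuple[int, int],
    circularity_threshold: Optional[float] = None,
    channel: str = "",
) -> FociSet:
    """Dual-threshold spot calling with size and optional circularity filters.

    A pixel is a candidate when ``image >= raw_threshold`` **and**
    ``equalized >= eq_threshold``; candidate connected components outside
    ``size_bounds``, or rounder than ``circularity_threshold`` permits when
    that filter is enabled, are discarded.
    """
    image = np.asarray(image, dtype=np.float64)
    equalized = np.asarray(equalized, dtype=np.float64)
    if image.shape != equalized.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs equalized {equalized.shape}"
        )
    lo, hi = size_bounds
    candidate = (image >= raw_threshold) & (equalized >= eq_threshold)
    foci: list[Focus] = []
    if candidate.any():
        labels = measure.label(candidate, connectivity=1)
        next_id = 1
        for region in measure.regionprops(labels):
            if not lo <= region.area <= hi:
                continue
            circ = _circularity(region)
            if circularity_threshold is not None and circ < circularity_threshold:
                continue
            rows, cols = region.coords[:, 0], region.coords[:, 1]
            foci.append(Focus(
                focus_id=next_id,
                rows=rows.copy(),
                cols=cols.copy(),
                area=int(region.area),
                circularity=circ,
            ))
            next_id += 1
    return FociSet(foci=foci, shape=image.shape, channel=channel)


def donut_ratio(
    focus: Focus,
    stain_image: np.ndarray,
    all_foci_mask: np.ndarray,
    dilation_radius: int,
) -> Optional[float]:
    """Mean stain intensity inside a focus over the mean in its dilated ring.

    The ring is the morphological dilation of the focus minus the focus
    itself minus *every* focus pixel in the field, so it never overlaps any
    focus.  Returns ``None`` (unscorable) when the ring is empty after
    clipping to the image, or its mean intensity is zero.
    """
    if dilation_radius <= 0:
        raise ValueError("dilation radius must be a positive integer")
    stain_image = np.asarray(stain_image, dtype=np.float64)
    focus_mask = np.zeros(stain_image.shape, dtype=bool)
    focus_mask[focus.rows, focus.cols] = True
    selem = morphology.disk(dilation_radius)
    donut = ndi.binary_dilation(focus_mask, structure=selem) & ~focus_mask & ~all_foci_mask
    if not donut.any():
        return None
    donut_mean = float(stain_image[donut].mean())
    if donut_mean == 0:
        return None
    focus_mean = float(stain_image[focus_mask].mean())
    return focus_mean / donut_mean


def classify_positive(ratio: Optional[float], threshold: float = 1.75) -> bool:
    """Strictly-greater-than positivity call; unscorable (None) is negative."""
    return ratio is not None and ratio > threshold


def score_foci(
    foci: FociSet,
    stain_image: np.ndarray,
    channel: str,
    dilation_radius: int = 2,
    threshold: float = 1.75,
) -> FociSet:
    """Attach donut ratio and positivity for one stain channel to every focus."""
    all_mask = foci.mask()
    for focus in foci:
        ratio = donut_ratio(focus, stain_image, all_mask, dilation_radius)
        focus.donut_ratio[channel] = ratio
        focus.positive[channel] = classify_positive(ratio, threshold)
    return foci


def assign_parents(foci: FociSet, cells: CellLabelMap) -> FociSet:
    """Assign each focus to the cell owning the majority of its pixels.

    Foci wholly in background keep ``parent_cell_id = None``.  Ties between
    cells break toward the smaller label for determinism.
    """
    if cells.labels.shape != foci.shape:
        raise ValueError(
            f"geometry mismatch: cells {cells.labels.shape} vs foci {foci.shape}"
        )
    for focus in foci:
        owners = cells.labels[focus.rows, focus.cols]
        owners = owners[owners > 0]
        if owners.size == 0:
            focus.parent_cell_id = None
        else:
            counts = np.bincount(owners)
            focus.parent_cell_id = int(counts.argmax())
    return foci


def analyze_foci(
    field: FieldImage,
    cells: CellLabelMap,
    config: AnalysisConfig,
    foci_channel: Optional[str] = None,
) -> FociSet:
    """Full foci chain for one field: detect, assign parents, score stains."""
    from .segmentation import background_subtract, foreground_otsu

    name = foci_channel or config.foci_channel
    channel = field.channel(name)
    # detection operates on the background-corrected channel so the automatic
    # raw threshold is meaningful even under strong uneven background
    corrected = background_subtract(channel, config.effective_background_scale)
    equalized = equalize(corrected, config.effective_equalize_sigma)
    raw_threshold = (config.foci_raw_threshold
                     if config.foci_raw_threshold is not None
                     else foreground_otsu(corrected))
    circ = config.circularity_threshold if name in config.circularity_channels else None
    foci = detect_foci(
        corrected,
        equalized,
        raw_threshold=raw_threshold,
        eq_threshold=config.eq_threshold,
        size_bounds=config.foci_size_bounds,
        circularity_threshold=circ,
        channel=name,
    )
    assign_parents(foci, cells)
    for stain in config.stain_channels:
        score_foci(
            foci,
            field.channel(stain),
            stain,
            dilation_radius=config.donut_radius,
            threshold=config.donut_threshold,
        )
    return foci
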