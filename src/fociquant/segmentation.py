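"""Single-cell segmentation by intensity/size masking and watershed splitting.

The strategy: estimate and subtract a smooth large-scale background, threshold
the segmentation channel into a cell mask, filter mask components by size,
then separate touching cells by blurring the channel, seeding a watershed at
the blurred regional maxima, and imposing the watershed separating lines on
the mask before relabelling connected components.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation as skseg
from skimage.feature import peak_local_max

from .model import AnalysisConfig, CellLabelMap, FieldImage

__all__ = [
    "background_subtract",
    "auto_threshold",
    "cell_mask",
    "watershed_split",
    "segment_field",
]


def background_subtract(image: np.ndarray, scale: float) -> np.ndarray:
    """Remove smooth background estimated as a wide Gaussian blur.

    ``scale`` (pixels) should be large relative to the objects of interest,
    by default 4x the expected cell radius.  The result is clipped at zero,
    so it is non-negative and pixel-wise no larger than the input wherever
    the background estimate is non-negative.
    """
    if scale <= 0:
        raise ValueError("background scale must be positive")
    image = np.asarray(image, dtype=np.float64)
    background = ndi.gaussian_filter(image, sigma=scale, mode="nearest")
    return np.clip(image - background, 0.0, None)


def auto_threshold(image: np.ndarray) -> float:
    """Otsu threshold; degenerate (constant) images get an unreachable threshold."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0 or np.ptp(image) == 0:
        return float(image.max(initial=0.0)) + 1.0
    return float(filters.threshold_otsu(image))


def foreground_otsu(image: np.ndarray) -> float:
    """Two-stage automatic threshold: Otsu applied to foreground pixels only.

    The first Otsu pass separates background from cells; the second pass,
    restricted to the foreground, separates bright compact structures (foci)
    from diffuse cytoplasmic signal.  Used as the default raw intensity gate
    for foci detection.
    """
    image = np.asarray(image, dtype=np.float64)
    first = auto_threshold(image)
    foreground = image[image >= first]
    if foreground.size < 2 or np.ptp(foreground) == 0:
        return first
    second = float(filters.threshold_otsu(foreground))
    # guard against images with no bright-spot class, where Otsu would bisect
    # the diffuse foreground itself: never gate below the robust upper fence
    # of the foreground distribution (median + 4 robust s.d.)
    median = float(np.median(foreground))
    sigma = 1.4826 * float(np.median(np.abs(foreground - median)))
    return max(second, median + 4.0 * sigma)


def cell_mask(
    image: np.ndarray,
    intensity_threshold: float,
    size_bounds: tuple[int, int],
) -> np.ndarray:
    """Threshold an image and keep connected components within size bounds."""
    lo, hi = size_bounds
    if lo > hi:
        raise ValueError(f"size bounds min {lo} exceeds max {hi}")
    mask = np.asarray(image, dtype=np.float64) >= intensity_threshold
    if not mask.any():
        return mask
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = (counts >= lo) & (counts <= hi)
    keep[0] = False
    return keep[labels]


def _seed_markers(blurred: np.ndarray, mask: np.ndarray, min_distance: int) -> np.ndarray:
    """Label regional maxima of the blurred image inside the mask.

    Plateau maxima are merged into one marker by labelling the peak-pixel
    mask; peak ordering (hence tie-breaking) follows scan order, which makes
    the seeding deterministic.
    """
    coords = peak_local_max(
        blurred,
        min_distance=min_distance,
        labels=mask,
        exclude_border=False,
    )
    peaks = np.zeros_like(mask, dtype=bool)
    peaks[tuple(coords.T)] = True
    markers, _ = ndi.label(peaks)
    return markers


def watershed_split(
    image: np.ndarray,
    mask: np.ndarray,
    blur_sigma: float,
    size_bounds: Optional[tuple[int, int]] = None,
    exclude_border: bool = False,
) -> CellLabelMap:
    """Split a cell mask into single cells along watershed lines.

    The image is Gaussian-blurred at ``blur_sigma``; the watershed is seeded
    from the blurred image's regional maxima (minimum seed separation equal
    to the blur sigma) and flooded downhill within the mask.  The separating
    lines are removed from the mask and the remaining connected components
    relabelled as cells; cells outside ``size_bounds`` are dropped.
    """
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return CellLabelMap.from_labels(np.zeros(mask.shape, dtype=np.int32))
    blurred = ndi.gaussian_filter(np.asarray(image, dtype=np.float64), blur_sigma,
                                  mode="nearest")
    min_distance = max(1, int(round(blur_sigma)))
    markers = _seed_markers(blurred, mask, min_distance)
    if markers.max() == 0:
        # flat plateau inside the mask: fall back to plain connected components
        labels = measure.label(mask, connectivity=1)
    else:
        ws = skseg.watershed(-blurred, markers=markers, mask=mask, watershed_line=True)
        labels = measure.label(ws > 0, connectivity=1)
    if exclude_border:
        border = np.unique(np.concatenate([
            labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
        ]))
        for b in border[border > 0]:
            labels[labels == b] = 0
    if size_bounds is not None:
        lo, hi = size_bounds
        counts = np.bincount(labels.ravel())
        bad = np.nonzero((counts < lo) | (counts > hi))[0]
        for b in bad[bad > 0]:
            labels[labels == b] = 0
    labels, _, _ = skseg.relabel_sequential(labels)
    return CellLabelMap.from_labels(labels)


def segment_field(field: FieldImage, config: AnalysisConfig) -> CellLabelMap:
    """Run the full segmentation chain on a field's segmentation channel."""
    channel = field.channel(config.segmentation_channel)
    corrected = background_subtract(channel, config.effective_background_scale)
    threshold = (config.cell_intensity_threshold
                 if config.cell_intensity_threshold is not None
                 else auto_threshold(corrected))
    mask = cell_mask(corrected, threshold, config.cell_size_bounds)
    return watershed_split(
        corrected,
        mask,
        config.effective_blur_sigma,
        size_bounds=config.cell_size_bounds,
        exclude_border=config.exclude_border_cells,
    )
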