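"""The two single-cell masks: DAPI nuclear and combined-lineage "targeted".

The nuclear mask thresholds the (smoothed) DAPI channel; it misses
chromatin-poor macrophages whose DAPI falls below threshold. The
targeted mask thresholds the pixelwise combination of the leukocyte
lineage channels (CD43/CD45/CD68/CD163 by default), recovers those
cells, and digitally excludes small or low-solidity cytoplasm
fragments. Comparing the two label counts gives the nuclear-over-
targeted yield ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops

from .model import DegenerateImageError, LabelMask, MultiplexImage, check_same_geometry

__all__ = [
    "SegmentationParams",
    "make_nuclear_mask",
    "make_targeted_mask",
    "exclude_fragments",
    "compare_mask_yield",
    "DEFAULT_LINEAGE_MARKERS",
]

DEFAULT_LINEAGE_MARKERS = ("CD43", "CD45", "CD68", "CD163")
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    threshold_method: str | float = "otsu"  # "otsu" or a fixed intensity
    min_area_um2: float = 12.0
    smoothing_sigma_um: float = 1.0
    combine_method: str = "max"  # or "sum"
    min_solidity: float = 0.5

    def __post_init__(self) -> None:
        if self.min_area_um2 <= 0:
            raise ValueError("min_area_um2 must be > 0")
        if self.combine_method not in ("max", "sum"):
            raise ValueError("combine_method must be 'max' or 'sum'")


def _threshold(img: np.ndarray, method: str | float) -> float:
    if isinstance(method, (int, float)):
        return float(method)
    if method == "otsu":
        return float(threshold_otsu(img))
    raise ValueError(f"unknown threshold method {method!r}")


def _segment_channel(img: np.ndarray, params: SegmentationParams,
                     pixel_size_um: float) -> np.ndarray:
    sigma_px = params.smoothing_sigma_um / pixel_size_um
    smooth = gaussian(img, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else img
    if np.ptp(smooth) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    binary = smooth > _threshold(smooth, params.threshold_method)
    labels, _ = ndimage.label(binary, structure=_EIGHT)
    return _filter_area(labels, params.min_area_um2, pixel_size_um)


def _filter_area(labels: np.ndarray, min_area_um2: float, pixel_size_um: float) -> np.ndarray:
    min_px = min_area_um2 / pixel_size_um**2
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_px)
    keep = keep[keep > 0]
    return _relabel(labels, keep)


def _relabel(labels: np.ndarray, keep: np.ndarray) -> np.ndarray:
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1)
    return lut[labels]


def make_nuclear_mask(image: MultiplexImage, params: SegmentationParams | None = None) -> LabelMask:
    """Smooth, threshold and label the DAPI channel (kind='nuclear')."""
    params = params or SegmentationParams()
    dapi = image.dapi(1)
    if dapi.std() == 0:
        raise DegenerateImageError("DAPI channel is constant")
    labels = _segment_channel(dapi, params, image.pixel_size_um)
    return LabelMask(labels=labels, kind="nuclear", pixel_size_um=image.pixel_size_um)


def make_targeted_mask(image: MultiplexImage, lineage_markers=None,
                       params: SegmentationParams | None = None) -> LabelMask:
    """Segment the combined leukocyte-lineage channels (kind='targeted').

    Each lineage channel is rescaled by its 99.9th percentile before the
    pixelwise combination so no single bright stain dominates; small or
    dendritic (low-solidity) fragments are then excluded.
    """
    params = params or SegmentationParams()
    if lineage_markers is None:
        lineage_markers = [m for m in DEFAULT_LINEAGE_MARKERS if m in image.panel.markers]
    lineage_markers = list(lineage_markers)
    if not lineage_markers:
        raise ValueError("lineage marker list is empty")
    scaled = []
    for m in lineage_markers:
        ch = image.channel(m)
        hi = np.percentile(ch, 99.9)
        scaled.append(ch / hi if hi > 0 else np.zeros_like(ch))
    combined = np.max(scaled, axis=0) if params.combine_method == "max" else np.sum(scaled, axis=0)
    labels = _segment_channel(combined, params, image.pixel_size_um)
    mask = LabelMask(labels=labels, kind="targeted", pixel_size_um=image.pixel_size_um)
    return exclude_fragments(mask, params.min_area_um2, params.min_solidity)


def exclude_fragments(mask: LabelMask, min_area_um2: float = 12.0,
                      min_solidity: float = 0.5) -> LabelMask:
    """Drop labels below an area or solidity floor; relabel 1..K.

    This is the digital exclusion of small dendritic-cytoplasm
    fragments: thin star-shaped objects have low solidity (object area
    over convex-hull area) while compact cells are near 1. Idempotent.
    """
    if mask.n_labels == 0:
        return LabelMask(labels=mask.labels.copy(), kind=mask.kind,
                         pixel_size_um=mask.pixel_size_um)
    min_px = min_area_um2 / mask.pixel_size_um**2
    keep = [p.label for p in regionprops(mask.labels)
            if p.area >= min_px and p.solidity >= min_solidity]
    labels = _relabel(mask.labels, np.asarray(keep, dtype=np.int64))
    return LabelMask(labels=labels, kind=mask.kind, pixel_size_um=mask.pixel_size_um)


def compare_mask_yield(nuclear: LabelMask, targeted: LabelMask) -> float:
    """Nuclear label count over targeted label count (NaN if targeted empty)."""
    check_same_geometry(nuclear, targeted)
    if targeted.n_labels == 0:
        return float("nan")
    return nuclear.n_labels / targeted.n_labels
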