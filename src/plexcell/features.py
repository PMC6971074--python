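"""Per-cell quantification: mean marker intensities, centroid and area."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import LabelMask, MultiplexImage
from .io import BASE_COLUMNS

__all__ = ["quantify", "density"]


def quantify(image: MultiplexImage, mask: LabelMask, case_id: str = "case") -> pd.DataFrame:
    """One row per label: unweighted centroid (µm), area (µm²) and the
    mean intensity of every panel marker over the label's pixels."""
    if image.shape != mask.labels.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.labels.shape}")
    if abs(image.pixel_size_um - mask.pixel_size_um) > 1e-9:
        raise ValueError("image and mask disagree on pixel size")
    px = image.pixel_size_um
    k = mask.n_labels
    table = pd.DataFrame({
        "cell_id": pd.Series(np.arange(1, k + 1), dtype=int),
        "case_id": case_id,
    })
    if k == 0:
        table = pd.DataFrame(columns=BASE_COLUMNS + list(image.panel.markers))
        return table.astype({"cell_id": int})
    index = np.arange(1, k + 1)
    com = ndimage.center_of_mass(np.ones_like(mask.labels), mask.labels, index)
    com = np.asarray(com)  # rows of (y, x) pixel indices
    areas = np.bincount(mask.labels.ravel(), minlength=k + 1)[1:]
    table["x_um"] = com[:, 1] * px
    table["y_um"] = com[:, 0] * px
    table["area_um2"] = areas * px**2
    for m in image.panel.markers:
        table[m] = ndimage.mean(image.channel(m), mask.labels, index)
    return table


def density(table: pd.DataFrame, area_mm2: float) -> float:
    """Cells per mm² of analyzed tissue."""
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be > 0")
    return len(table) / area_mm2
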