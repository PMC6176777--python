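"""Sunlit-vegetation segmentation via excess-green thresholding.

Both bare soil and shaded pixels have lower excess green (ExG = 2 rho_G -
rho_R - rho_B) than sunlit canopy, so a single threshold on the ExG map
(default 0.046) separates sunlit vegetation from everything that would bias
spectral traits — including cast shadows whose NDVI is spuriously high.
ExG is computed from the blue/green/red bands of the multispectral stack by
default, since the resulting mask is applied to index rasters on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo_io import BandStack, GridGeometry
from .scene_sim import LABELS

__all__ = ["Mask", "compute_exg", "sunlit_vegetation_mask", "mask_statistics"]


@dataclass
class Mask:
    """Boolean raster; True marks sunlit vegetation."""

    values: np.ndarray
    grid: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid geometry")


def compute_exg(stack: BandStack) -> np.ndarray:
    """Excess-green map 2*green - red - blue; NaN (nodata) propagates."""
    return 2.0 * stack.band("green") - stack.band("red") - stack.band("blue")


def sunlit_vegetation_mask(stack: BandStack, threshold: float = 0.046) -> Mask:
    """Mask of pixels with ExG strictly above the threshold.

    Pixels exactly at the threshold count as background (the filter's intent
    is to exclude low values); nodata pixels are never vegetation.
    """
    if not np.isfinite(threshold) and not np.isinf(threshold):
        raise ValueError("threshold must be a number")
    exg = compute_exg(stack)
    with np.errstate(invalid="ignore"):
        values = exg > threshold
    return Mask(values, stack.grid)


def mask_statistics(mask: Mask, labels: np.ndarray) -> pd.DataFrame:
    """2 x 4 confusion table of the mask against the simulator's class labels.

    Rows are mask True/False, columns the four pixel classes; entries are
    pixel counts and sum to the raster size.
    """
    labels = np.asarray(labels)
    if labels.shape != mask.values.shape:
        raise ValueError("label raster shape does not match the mask")
    table = pd.DataFrame(
        0, index=["mask_true", "mask_false"], columns=list(LABELS), dtype=int
    )
    for name, code in LABELS.items():
        sel = labels == code
        table.loc["mask_true", name] = int(np.count_nonzero(mask.values & sel))
        table.loc["mask_false", name] = int(np.count_nonzero(~mask.values & sel))
    return table
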