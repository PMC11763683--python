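"""Grey-level discretisation of a masked ROI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EmptyMask", "QuantisedRoi", "quantise"]


class EmptyMask(ValueError):
    """The ROI mask selects no pixels."""


@dataclass(frozen=True)
class QuantisedRoi:
    """Discretised ROI: ``levels`` holds values 1..Ng inside the mask and 0
    outside (background sentinel)."""

    levels: np.ndarray  # int, (H, W); 0 = background
    mask: np.ndarray  # bool, (H, W)
    n_levels: int

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def grey_levels(self) -> np.ndarray:
        """Distinct levels actually occupied, ascending."""
        return np.unique(self.levels[self.mask])


def quantise(image: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> QuantisedRoi:
    """Equal-width binning of ROI intensities into levels 1..n_levels.

    Bin edges span [min, max] of the ROI; the maximum intensity maps to
    level ``n_levels``.  A constant ROI maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise EmptyMask("mask selects no pixels")
    vals = np.asarray(image, dtype=float)[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(image.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
    else:
        width = (hi - lo) / n_levels
        binned = np.floor((vals - lo) / width).astype(np.int64) + 1
        levels[mask] = np.minimum(binned, n_levels)
    return QuantisedRoi(levels=levels, mask=mask, n_levels=n_levels)
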