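"""Rule-based L1-L4 ROI mask generation from annotated spine images.

The scanner software draws the lateral spine contours in black (grey value
0) and the vertebra dividers as white horizontal segments at the maximum
grey value.  The mask algorithm recovers exactly those overlay pixels and
fills the region they enclose:

1. trace the left contour by scanning each row from the left edge to the
   middle of the image, accepting zero-valued pixels whose right-hand
   neighbourhood is brighter than the left-hand one and which remain
   8-connected to the previous row's accepted pixel;
2. trace the right contour symmetrically from the right edge;
3. locate the first white horizontal segment from the top (upper boundary
   of L1) and from the bottom (lower boundary of L4);
4. draw the boundary pixels on a black canvas and flood-fill the enclosed
   interior.

The algorithm is exact, not approximate: on clean annotated input the mask
equals the ground-truth ROI pixel for pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.segmentation import flood

__all__ = [
    "SegmentationError",
    "NoContourFound",
    "NoDividerFound",
    "MaskNotClosed",
    "ContourTrace",
    "RoiVertices",
    "find_contour",
    "find_roi_vertices",
    "build_mask",
]


class SegmentationError(Exception):
    """Base class for mask-generation failures."""


class NoContourFound(SegmentationError):
    """No row yielded an accepted contour pixel (non-annotated image)."""


class NoDividerFound(SegmentationError):
    """Fewer than two white divider segments exist."""


class MaskNotClosed(SegmentationError):
    """The boundary does not enclose a bounded region (fill would leak)."""


@dataclass(frozen=True)
class ContourTrace:
    side: Literal["left", "right"]
    points: np.ndarray  # (n, 2) array of (row, col), ordered top to bottom

    def columns_by_row(self) -> dict[int, int]:
        return {int(r): int(c) for r, c in self.points}


@dataclass(frozen=True)
class RoiVertices:
    """Rows bounding the L1-L4 enclosing rectangle."""

    top_row: int
    bottom_row: int

    def __post_init__(self) -> None:
        if not self.top_row < self.bottom_row:
            raise ValueError("top_row must be above bottom_row")


def _neighbour_means(row: np.ndarray, col: int, window: int) -> tuple[float, float]:
    """Mean intensity of up to ``window`` pixels immediately left and right
    of ``col`` on the same row, truncated at the image borders."""
    left = row[max(0, col - window):col]
    right = row[col + 1:col + 1 + window]
    lmean = float(left.mean()) if left.size else -np.inf
    rmean = float(right.mean()) if right.size else -np.inf
    return lmean, rmean


def find_contour(pixels: np.ndarray, side: Literal["left", "right"],
                 neighbourhood: int = 5) -> ContourTrace:
    """Trace one lateral spine contour.

    Scans every row top to bottom.  For ``side='left'`` candidate columns
    run from the left edge up to (excluding) floor(width/2); zero-valued
    pixels are accepted when the mean intensity to their right exceeds the
    mean to their left (ties rejected), reversed for ``side='right'``.
    After the first accepted row, a pixel must also be 8-connected to the
    previously accepted pixel (accepted on the immediately preceding row,
    column within +-1).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    h, w = pixels.shape
    half = w // 2

    points: list[tuple[int, int]] = []
    prev: tuple[int, int] | None = None
    for r in range(h):
        row = pixels[r]
        if side == "left":
            candidates = np.flatnonzero(row[:half] == 0)
        else:
            candidates = (np.flatnonzero(row[half:] == 0) + half)[::-1]
        accepted = None
        for c in candidates:
            c = int(c)
            lmean, rmean = _neighbour_means(row, c, neighbourhood)
            inward_brighter = rmean > lmean if side == "left" else lmean > rmean
            if not inward_brighter:
                continue
            if prev is not None:
                pr, pc = prev
                if r - pr != 1 or abs(c - pc) > 1:
                    continue  # not 8-connected to the running trace
            accepted = (r, c)
            break
        if accepted is not None:
            points.append(accepted)
            prev = accepted
    if not points:
        raise NoContourFound(f"no {side} contour pixel accepted in any row")
    return ContourTrace(side=side, points=np.array(points, dtype=int))


def _white_segment_rows(pixels: np.ndarray, min_segment: int) -> np.ndarray:
    """Rows containing a horizontal run of >= min_segment pixels at the
    maximum representable grey value."""
    white_value = np.iinfo(pixels.dtype).max if pixels.dtype.kind == "u" else pixels.max()
    is_white = pixels == white_value
    rows = []
    for r in range(pixels.shape[0]):
        line = is_white[r]
        if not line.any():
            continue
        # longest run of consecutive True
        padded = np.concatenate([[0], line.view(np.int8), [0]])
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        if starts.size and (ends - starts).max() >= min_segment:
            rows.append(r)
    return np.array(rows, dtype=int)


def find_roi_vertices(pixels: np.ndarray, min_segment: int = 10) -> RoiVertices:
    """Locate the rows of the L1 upper and L4 lower divider segments.

    ``top_row`` is the first qualifying white segment scanning down from
    the top edge; ``bottom_row`` the first scanning up from the bottom.
    Segments shorter than ``min_segment`` pixels are rejected as speckle.
    """
    rows = _white_segment_rows(pixels, min_segment)
    if rows.size < 2:
        raise NoDividerFound("fewer than two white divider segments found")
    return RoiVertices(top_row=int(rows.min()), bottom_row=int(rows.max()))


def build_mask(pixels: np.ndarray, neighbourhood: int = 5,
               min_segment: int = 10) -> np.ndarray:
    """Produce the binary L1-L4 ROI mask (bool array, True inside the ROI).

    Boundary pixels are the two contour traces clipped to the divider row
    range plus the top/bottom divider rows spanning between the contours;
    the enclosed interior is filled with a 4-connected flood fill seeded at
    the centroid of the bounding rectangle.  A fill that reaches the image
    border raises :class:`MaskNotClosed`.
    """
    left = find_contour(pixels, "left", neighbourhood)
    right = find_contour(pixels, "right", neighbourhood)
    v = find_roi_vertices(pixels, min_segment)

    h, w = pixels.shape
    lcols = left.columns_by_row()
    rcols = right.columns_by_row()

    boundary = np.zeros((h, w), dtype=bool)
    for r in range(v.top_row, v.bottom_row + 1):
        lc, rc = lcols.get(r), rcols.get(r)
        if lc is not None:
            boundary[r, lc] = True
        if rc is not None:
            boundary[r, rc] = True
    for r in (v.top_row, v.bottom_row):
        lc, rc = lcols.get(r), rcols.get(r)
        if lc is not None and rc is not None and rc > lc:
            boundary[r, lc:rc + 1] = True

    mid = (v.top_row + v.bottom_row) // 2
    lc, rc = lcols.get(mid), rcols.get(mid)
    if lc is None or rc is None or rc - lc < 2:
        raise MaskNotClosed("contours do not span the ROI row range")
    seed = (mid, (lc + rc) // 2)
    if boundary[seed]:
        raise MaskNotClosed("degenerate ROI: no interior at the seed row")

    interior = flood(boundary, seed, connectivity=1)  # connected non-boundary
    if (interior[0, :].any() or interior[-1, :].any()
            or interior[:, 0].any() or interior[:, -1].any()):
        raise MaskNotClosed("flood fill leaked to the image border")
    return interior | boundary
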