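"""Construction of the five 2D grey-level texture matrices.

All matrices are computed over the ROI only (pixel pairs, runs, zones and
neighbourhoods never cross the mask boundary).  Analysis is planar with
distance-1 offsets in the four 2D directions (0deg, 90deg, 45deg, 135deg);
per-direction matrices are kept separate so features can be averaged over
angles, as is conventional for 2D radiomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .quantise import QuantisedRoi

__all__ = [
    "OFFSETS_2D",
    "TextureMatrix",
    "glcm",
    "glrlm",
    "glszm",
    "gldm",
    "ngtdm",
]

# distance-1 offsets (drow, dcol): horizontal, vertical, both diagonals
OFFSETS_2D: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class TextureMatrix:
    """A grey-level texture matrix with its construction parameters.

    For directional families (GLCM, GLRLM) ``values`` has one matrix per
    offset stacked on axis 0; for GLSZM/GLDM it is a single 2D matrix and
    for NGTDM a (Ng, 3) array of [p_i, s_i, n_i] rows.
    """

    family: str
    values: np.ndarray
    parameters: dict = field(default_factory=dict)


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray,
                   offset: tuple[int, int]):
    """Index arrays of in-ROI pixel pairs related by ``offset``."""
    dr, dc = offset
    h, w = levels.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a_mask = mask[r0s:r0e, c0s:c0e]
    b_mask = mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    both = a_mask & b_mask
    a = levels[r0s:r0e, c0s:c0e][both]
    b = levels[r0s + dr:r0e + dr, c0s + dc:c0e + dc][both]
    return a, b


def glcm(q: QuantisedRoi) -> TextureMatrix:
    """Symmetric grey-level co-occurrence matrices, one per offset.

    Entry (i, j) counts in-ROI pixel pairs at the offset with levels
    (i+1, j+1), symmetrised (each pair counted in both orders).
    """
    ng = q.n_levels
    out = np.zeros((len(OFFSETS_2D), ng, ng), dtype=np.int64)
    for k, off in enumerate(OFFSETS_2D):
        a, b = _shifted_pairs(q.levels, q.mask, off)
        np.add.at(out[k], (a - 1, b - 1), 1)
        np.add.at(out[k], (b - 1, a - 1), 1)
    return TextureMatrix("GLCM", out, {"offsets": OFFSETS_2D, "distance": 1})


def _lines(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int]):
    """Yield every maximal 1D scan line of the image along ``offset`` as a
    level array with 0 marking out-of-ROI pixels."""
    lv = np.where(mask, levels, 0)
    dr, dc = offset
    if (dr, dc) == (0, 1):
        yield from lv
    elif (dr, dc) == (1, 0):
        yield from lv.T
    elif (dr, dc) == (1, 1):
        h, w = lv.shape
        for d in range(-(h - 1), w):
            yield np.diagonal(lv, offset=d)
    elif (dr, dc) == (1, -1):
        fl = lv[:, ::-1]
        h, w = fl.shape
        for d in range(-(h - 1), w):
            yield np.diagonal(fl, offset=d)
    else:  # pragma: no cover - fixed offset set
        raise ValueError(f"unsupported offset {offset}")


def _run_lengths(line: np.ndarray):
    """(level, run_length) pairs of maximal equal-level runs, skipping the
    background sentinel 0."""
    n = line.size
    if n == 0:
        return
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [n]])
    for s, e in zip(starts, ends):
        g = int(line[s])
        if g != 0:
            yield g, int(e - s)


def glrlm(q: QuantisedRoi) -> TextureMatrix:
    """Grey-level run-length matrices R(g, l), one per direction."""
    ng = q.n_levels
    max_len = max(q.levels.shape)
    out = np.zeros((len(OFFSETS_2D), ng, max_len), dtype=np.int64)
    for k, off in enumerate(OFFSETS_2D):
        for line in _lines(q.levels, q.mask, off):
            for g, ln in _run_lengths(np.ascontiguousarray(line)):
                out[k, g - 1, ln - 1] += 1
    return TextureMatrix("GLRLM", out, {"offsets": OFFSETS_2D})


def glszm(q: QuantisedRoi) -> TextureMatrix:
    """Grey-level size-zone matrix S(g, z) over 8-connected equal-level
    zones (single matrix; zones have no direction)."""
    ng = q.n_levels
    sizes_by_level: list[np.ndarray] = []
    max_zone = 1
    for g in range(1, ng + 1):
        comp = cc_label((q.levels == g) & q.mask, connectivity=2)
        if comp.max() == 0:
            sizes_by_level.append(np.empty(0, dtype=np.int64))
            continue
        sizes = np.bincount(comp.ravel())[1:]
        sizes_by_level.append(sizes)
        max_zone = max(max_zone, int(sizes.max()))
    out = np.zeros((ng, max_zone), dtype=np.int64)
    for g, sizes in enumerate(sizes_by_level, start=1):
        for s in sizes:
            out[g - 1, s - 1] += 1
    return TextureMatrix("GLSZM", out, {"connectivity": 8})


def gldm(q: QuantisedRoi, alpha: int = 0, delta: int = 1) -> TextureMatrix:
    """Grey-level dependence matrix D(g, j).

    A neighbour within Chebyshev distance ``delta`` is dependent when its
    level differs from the centre by at most ``alpha``.  The dependence
    index is j = (number of dependent neighbours) + 1, so the centre pixel
    itself always contributes; j therefore runs 1..(neighbourhood size + 1).
    """
    offsets = [(dr, dc)
               for dr in range(-delta, delta + 1)
               for dc in range(-delta, delta + 1)
               if (dr, dc) != (0, 0)]
    dep = np.zeros(q.levels.shape, dtype=np.int64)
    for off in offsets:
        dr, dc = off
        h, w = q.levels.shape
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        centre_m = q.mask[r0s:r0e, c0s:c0e]
        nb_m = q.mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        both = centre_m & nb_m
        diff = np.abs(q.levels[r0s:r0e, c0s:c0e]
                      - q.levels[r0s + dr:r0e + dr, c0s + dc:c0e + dc])
        dep[r0s:r0e, c0s:c0e] += (both & (diff <= alpha)).astype(np.int64)
    g = q.levels[q.mask]
    j = dep[q.mask] + 1
    out = np.zeros((q.n_levels, len(offsets) + 1), dtype=np.int64)
    np.add.at(out, (g - 1, j - 1), 1)
    return TextureMatrix("GLDM", out, {"alpha": alpha, "delta": delta})


def ngtdm(q: QuantisedRoi, delta: int = 1) -> TextureMatrix:
    """Neighbouring grey-tone difference matrix.

    Per occupied level i: p_i (fraction of valid ROI pixels), s_i (summed
    absolute difference between level i pixels and the mean level of their
    in-ROI neighbours) and n_i (pixel count).  Pixels with no in-ROI
    neighbour are excluded.  ``values`` is an (Ng, 3) array [p, s, n].
    """
    offsets = [(dr, dc)
               for dr in range(-delta, delta + 1)
               for dc in range(-delta, delta + 1)
               if (dr, dc) != (0, 0)]
    h, w = q.levels.shape
    nb_sum = np.zeros((h, w), dtype=np.float64)
    nb_cnt = np.zeros((h, w), dtype=np.int64)
    for dr, dc in offsets:
        r0s, r0e = max(0, -dr), min(h, h - dr)
        c0s, c0e = max(0, -dc), min(w, w - dc)
        nb_m = q.mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        nb_sum[r0s:r0e, c0s:c0e] += np.where(
            nb_m, q.levels[r0s + dr:r0e + dr, c0s + dc:c0e + dc], 0)
        nb_cnt[r0s:r0e, c0s:c0e] += nb_m.astype(np.int64)
    valid = q.mask & (nb_cnt > 0)
    levels = q.levels[valid]
    diffs = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
    out = np.zeros((q.n_levels, 3), dtype=np.float64)
    n_valid = int(valid.sum())
    for g in range(1, q.n_levels + 1):
        sel = levels == g
        n_i = int(sel.sum())
        out[g - 1, 1] = diffs[sel].sum()
        out[g - 1, 2] = n_i
    if n_valid > 0:
        out[:, 0] = out[:, 2] / n_valid
    return TextureMatrix("NGTDM", out, {"delta": delta})
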