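"""Independent brute-force oracles for the texture matrices.

Every function here enumerates pixels, pairs, runs, zones or
neighbourhoods with plain Python loops, sharing no code with the
implementation under test.  They are only intended for tiny ROIs.
"""

from __future__ import annotations

import numpy as np

OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
EIGHT = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
         if (dr, dc) != (0, 0)]


def _in(levels, mask, r, c):
    h, w = levels.shape
    return 0 <= r < h and 0 <= c < w and mask[r, c]


def glcm_brute(levels, mask, ng):
    """Pairwise enumeration of in-ROI pixel pairs per offset (symmetric)."""
    h, w = levels.shape
    out = np.zeros((len(OFFSETS), ng, ng), dtype=np.int64)
    for k, (dr, dc) in enumerate(OFFSETS):
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                r2, c2 = r + dr, c + dc
                if _in(levels, mask, r2, c2):
                    a, b = levels[r, c], levels[r2, c2]
                    out[k, a - 1, b - 1] += 1
                    out[k, b - 1, a - 1] += 1
    return out


def glrlm_brute(levels, mask, ng, max_len):
    """Linear scan of maximal equal-level runs per direction."""
    h, w = levels.shape
    out = np.zeros((len(OFFSETS), ng, max_len), dtype=np.int64)
    for k, (dr, dc) in enumerate(OFFSETS):
        # starting points: pixels with no predecessor along the direction
        for r in range(h):
            for c in range(w):
                if dr == 0 and dc == 1:
                    start = c == 0
                elif dr == 1 and dc == 0:
                    start = r == 0
                elif dr == 1 and dc == 1:
                    start = r == 0 or c == 0
                else:  # (1, -1)
                    start = r == 0 or c == w - 1
                if not start:
                    continue
                # walk the whole scan line, emitting runs of in-ROI levels
                rr, cc = r, c
                cur, length = None, 0
                while 0 <= rr < h and 0 <= cc < w:
                    g = levels[rr, cc] if mask[rr, cc] else 0
                    if g == cur:
                        length += 1
                    else:
                        if cur not in (None, 0):
                            out[k, cur - 1, length - 1] += 1
                        cur, length = g, 1
                    rr += dr
                    cc += dc
                if cur not in (None, 0):
                    out[k, cur - 1, length - 1] += 1
    return out


def glszm_brute(levels, mask, ng, max_zone):
    """Flood-fill (BFS, 8-connected) enumeration of equal-level zones."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    out = np.zeros((ng, max_zone), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            g = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in EIGHT:
                    r2, c2 = rr + dr, cc + dc
                    if (_in(levels, mask, r2, c2) and not seen[r2, c2]
                            and levels[r2, c2] == g):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            out[g - 1, size - 1] += 1
    return out


def gldm_brute(levels, mask, ng, alpha=0, delta=1):
    """Per-pixel neighbour enumeration; dependence index = count + 1."""
    h, w = levels.shape
    nbhd = [(dr, dc) for dr in range(-delta, delta + 1)
            for dc in range(-delta, delta + 1) if (dr, dc) != (0, 0)]
    out = np.zeros((ng, len(nbhd) + 1), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            d = 0
            for dr, dc in nbhd:
                r2, c2 = r + dr, c + dc
                if (_in(levels, mask, r2, c2)
                        and abs(int(levels[r, c]) - int(levels[r2, c2])) <= alpha):
                    d += 1
            out[levels[r, c] - 1, d] += 1
    return out


def ngtdm_brute(levels, mask, ng, delta=1):
    """Per-pixel neighbour-mean enumeration; returns (Ng, 3) [p, s, n]."""
    h, w = levels.shape
    nbhd = [(dr, dc) for dr in range(-delta, delta + 1)
            for dc in range(-delta, delta + 1) if (dr, dc) != (0, 0)]
    s = np.zeros(ng)
    n = np.zeros(ng)
    n_valid = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            vals = [levels[r2, c2] for dr, dc in nbhd
                    if _in(levels, mask, (r2 := r + dr), (c2 := c + dc))]
            if not vals:
                continue
            n_valid += 1
            g = levels[r, c]
            s[g - 1] += abs(g - sum(vals) / len(vals))
            n[g - 1] += 1
    out = np.zeros((ng, 3))
    out[:, 1] = s
    out[:, 2] = n
    if n_valid:
        out[:, 0] = n / n_valid
    return out


def quantise_brute(values, lo, hi, n_levels):
    """Independent re-binning loop for equal-width quantisation."""
    if hi == lo:
        return np.ones(len(values), dtype=int)
    width = (hi - lo) / n_levels
    out = []
    for v in values:
        lev = int((v - lo) // width) + 1
        out.append(min(lev, n_levels))
    return np.array(out)


def confusion_brute(y_true, y_pred, positive=1):
    """Plain-loop confusion counts."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if p == positive:
            if t == positive:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn
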