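"""Nested-loop brute-force oracles for the morphological primitives.

Deliberately naive: every operation is written as an explicit pixel/window
loop or an iterate-until-stability fixpoint, independent of the library
implementations they check.
"""

from __future__ import annotations

import numpy as np


def _clamp(v: int, lo: int, hi: int) -> int:
    return lo if v < lo else hi if v > hi else v


def erode(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Min filter over the SE window with edge replication."""
    h, w = img.shape
    sh, sw = se.shape
    oy, ox = sh // 2, sw // 2
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = []
            for i in range(sh):
                for j in range(sw):
                    if se[i, j]:
                        rr = _clamp(r + i - oy, 0, h - 1)
                        cc = _clamp(c + j - ox, 0, w - 1)
                        vals.append(img[rr, cc])
            out[r, c] = min(vals)
    return out


def dilate(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Max filter over the reflected SE window with edge replication."""
    h, w = img.shape
    sh, sw = se.shape
    oy, ox = sh // 2, sw // 2
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = []
            for i in range(sh):
                for j in range(sw):
                    if se[i, j]:
                        rr = _clamp(r - (i - oy), 0, h - 1)
                        cc = _clamp(c - (j - ox), 0, w - 1)
                        vals.append(img[rr, cc])
            out[r, c] = max(vals)
    return out


def opening(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    return dilate(erode(img, se), se)


def closing(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    return erode(dilate(img, se), se)


def co_filter(img: np.ndarray) -> np.ndarray:
    se = np.ones((3, 3), dtype=bool)
    return opening(closing(img, se), se)


def reconstruct_by_dilation(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Iterate dilate-then-min with the 8-connected unit SE until stable."""
    se = np.ones((3, 3), dtype=bool)
    cur = np.minimum(marker, mask)
    while True:
        nxt = np.minimum(dilate(cur, se), mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def reconstruct_by_erosion(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    se = np.ones((3, 3), dtype=bool)
    cur = np.maximum(marker, mask)
    while True:
        nxt = np.maximum(erode(cur, se), mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def h_convexity(img: np.ndarray, h: int) -> np.ndarray:
    wide = img.astype(np.int64)
    return wide - reconstruct_by_dilation(np.maximum(wide - h, 0), wide)


def minima_imposition(img: np.ndarray, marker: np.ndarray) -> np.ndarray:
    wide = img.astype(np.int64)
    sentinel = int(wide.max()) + 2
    f_m = np.where(marker, 0, sentinel)
    return reconstruct_by_erosion(f_m, np.minimum(wide + 1, f_m))


def _neighbors(r: int, c: int, h: int, w: int, connectivity: int):
    if connectivity == 8:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    for dr, dc in offs:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            yield rr, cc


def regional_minima(img: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Enumerate equal-value plateaus; keep those with no lower border pixel."""
    h, w = img.shape
    seen = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for r0 in range(h):
        for c0 in range(w):
            if seen[r0, c0]:
                continue
            level = img[r0, c0]
            plateau = [(r0, c0)]
            seen[r0, c0] = True
            stack = [(r0, c0)]
            is_min = True
            while stack:
                r, c = stack.pop()
                for rr, cc in _neighbors(r, c, h, w, connectivity):
                    if img[rr, cc] == level:
                        if not seen[rr, cc]:
                            seen[rr, cc] = True
                            plateau.append((rr, cc))
                            stack.append((rr, cc))
                    elif img[rr, cc] < level:
                        is_min = False
            if is_min:
                for r, c in plateau:
                    out[r, c] = True
    return out


def area_filter(mask: np.ndarray, min_px: int, max_px: int) -> np.ndarray:
    """Label 8-connected components by flood fill; keep sizes in range."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = [(r0, c0)]
                seen[r0, c0] = True
                stack = [(r0, c0)]
                while stack:
                    r, c = stack.pop()
                    for rr, cc in _neighbors(r, c, h, w, 8):
                        if mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            comp.append((rr, cc))
                            stack.append((rr, cc))
                if min_px <= len(comp) <= max_px:
                    for r, c in comp:
                        out[r, c] = True
    return out
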