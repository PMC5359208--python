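"""Flat grayscale and binary morphological primitives.

Everything downstream (the multiscale detector and the marker-controlled
watershed) is composed from the operations in this module: flat erosion and
dilation with small structuring elements, the alternating closing-opening
filter, grayscale reconstruction, the h-convexity residue, regional minima,
minima imposition, the immersion watershed with explicit divide lines, and
the binary cleaning steps (area filtering, hole closing, border-object
removal).

Conventions
-----------
* Images are 2-D numpy arrays, (row, col) indexed, 0-based.  Inputs are
  8-bit; intermediates may be wider integers.
* Structuring elements are flat (boolean footprints): the 3x3 square and
  1-px-thick centered lines of odd length in four orientations.
* Borders are handled by edge replication, so a flat image is a fixed point
  of every filter and no phantom responses appear at ROI edges.
* Connectivity: 8-neighborhood for regional minima, connected components and
  watershed flooding; 4-connected background for hole filling (the standard
  dual pairing).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima
from skimage.morphology import reconstruction as _sk_reconstruction

__all__ = [
    "square3",
    "line_se",
    "erode",
    "dilate",
    "opening",
    "closing",
    "co_filter",
    "reconstruct_by_dilation",
    "binary_reconstruct",
    "h_convexity",
    "threshold",
    "regional_minima",
    "minima_imposition",
    "watershed",
    "area_filter",
    "fill_holes",
    "remove_border_objects",
]

#: 8-neighborhood structure used for component labeling and flooding.
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndi.generate_binary_structure(2, 1)

_LINE_ORIENTATIONS = ("horizontal", "vertical", "diag_left", "diag_right")


# ---------------------------------------------------------------------------
# Structuring elements
# ---------------------------------------------------------------------------

def square3() -> np.ndarray:
    """The 3x3 square structuring element, origin at center."""
    return np.ones((3, 3), dtype=bool)


def line_se(orientation: str, length: int) -> np.ndarray:
    """A 1-px-thick centered linear structuring element of odd ``length``.

    Parameters
    ----------
    orientation:
        One of ``horizontal``, ``vertical``, ``diag_left`` (running from
        top-left to bottom-right) or ``diag_right`` (top-right to
        bottom-left).
    length:
        Number of pixels along the line; must be odd so the origin sits at
        the center.
    """
    if orientation not in _LINE_ORIENTATIONS:
        raise ValueError(f"unknown line orientation {orientation!r}")
    if length < 1 or length % 2 == 0:
        raise ValueError(f"line length must be odd and >= 1, got {length}")
    if orientation == "horizontal":
        return np.ones((1, length), dtype=bool)
    if orientation == "vertical":
        return np.ones((length, 1), dtype=bool)
    if orientation == "diag_left":
        return np.eye(length, dtype=bool)
    return np.fliplr(np.eye(length, dtype=bool))


def _check_se(se: np.ndarray) -> np.ndarray:
    se = np.asarray(se)
    if se.ndim != 2 or se.size == 0 or not se.any():
        raise ValueError("structuring element must be a non-empty 2-D footprint")
    return se.astype(bool)


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    return img


# ---------------------------------------------------------------------------
# Erosion / dilation and the alternating filters
# ---------------------------------------------------------------------------

def erode(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Flat erosion: pointwise minimum over the SE window (edge-replicated)."""
    img = _check_image(img)
    se = _check_se(se)
    return ndi.grey_erosion(img, footprint=se, mode="nearest")


def dilate(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Flat dilation: pointwise maximum over the reflected SE window."""
    img = _check_image(img)
    se = _check_se(se)
    return ndi.grey_dilation(img, footprint=se, mode="nearest")


def opening(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Morphological opening: erosion followed by dilation."""
    return dilate(erode(img, se), se)


def closing(img: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Morphological closing: dilation followed by erosion."""
    return erode(dilate(img, se), se)


def co_filter(img: np.ndarray) -> np.ndarray:
    """Closing-opening alternating filter with the 3x3 square.

    Idempotent; suppresses isolated bright spikes and dark pits while
    leaving larger structures intact.  Used both to build the morphological
    pyramid and to precondition the image for the watershed.
    """
    se = square3()
    return opening(closing(img, se), se)


# ---------------------------------------------------------------------------
# Reconstruction and derived transforms
# ---------------------------------------------------------------------------

def reconstruct_by_dilation(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Grayscale reconstruction by dilation of ``marker`` under ``mask``.

    Iterated geodesic dilation (8-connected) until stability.  The marker is
    clipped down to the mask where it exceeds it, since callers construct
    markers by saturating arithmetic that can overshoot.
    """
    marker = _check_image(marker)
    mask = _check_image(mask)
    if marker.shape != mask.shape:
        raise ValueError("marker and mask shapes differ")
    marker = np.minimum(marker, mask)
    out = _sk_reconstruction(marker, mask, method="dilation", footprint=_STRUCT8)
    return out.astype(mask.dtype, copy=False)


def binary_reconstruct(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Binary reconstruction: connected components of ``mask`` hit by ``marker``.

    Equivalent to grayscale reconstruction by dilation on 0/1 images, but
    computed by component labeling (8-connectivity).
    """
    marker = _check_image(marker).astype(bool)
    mask = _check_image(mask).astype(bool)
    if marker.shape != mask.shape:
        raise ValueError("marker and mask shapes differ")
    labels, n = ndi.label(mask, structure=_STRUCT8)
    if n == 0:
        return np.zeros_like(mask)
    hit = np.unique(labels[marker & mask])
    hit = hit[hit > 0]
    return np.isin(labels, hit)


def h_convexity(img: np.ndarray, h: int) -> np.ndarray:
    """Residue of the h-maxima transform: ``img - R_dil(img - h, img)``.

    Positive exactly on maxima domes standing less than ``h`` gray levels
    below their local peak; values lie in [0, h].  Thresholding the residue
    at 1 yields the support of the extended maxima.
    """
    img = _check_image(img)
    if h < 1:
        raise ValueError(f"h must be >= 1, got {h}")
    wide = img.astype(np.int64)
    marker = np.maximum(wide - int(h), 0)
    rec = reconstruct_by_dilation(marker, wide)
    return wide - rec


def threshold(img: np.ndarray, t: int) -> np.ndarray:
    """Binary mask true where ``img >= t`` (values below ``t`` are dropped)."""
    return _check_image(img) >= t


# ---------------------------------------------------------------------------
# Regional minima, minima imposition, watershed
# ---------------------------------------------------------------------------

def _connectivity_value(connectivity: int) -> int:
    if connectivity == 4:
        return 1
    if connectivity == 8:
        return 2
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def regional_minima(img: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Mask of regional minima: plateaus with no strictly lower neighbor."""
    img = _check_image(img)
    if img.min() == img.max():
        # single plateau covering the whole image
        return np.ones_like(img, dtype=bool)
    return local_minima(img, connectivity=_connectivity_value(connectivity))


def minima_imposition(img: np.ndarray, marker: np.ndarray) -> np.ndarray:
    """Force the regional minima of ``img`` to coincide with ``marker``.

    Standard formulation: reconstruction by erosion of
    ``min(img + 1, f_m)`` from ``f_m``, where ``f_m`` is 0 on the marker and
    a maximal sentinel elsewhere.  Every 8-connected marker component
    becomes a regional minimum at level 0 and all other minima are flooded
    out.  Returns a wide-integer image.
    """
    img = _check_image(img)
    marker = _check_image(marker).astype(bool)
    if img.shape != marker.shape:
        raise ValueError("image and marker shapes differ")
    if not marker.any():
        raise ValueError("marker must contain at least one pixel")
    wide = img.astype(np.int64)
    sentinel = int(wide.max()) + 2
    f_m = np.where(marker, 0, sentinel)
    mask = np.minimum(wide + 1, f_m)
    out = _sk_reconstruction(f_m, mask, method="erosion", footprint=_STRUCT8)
    return out.astype(np.int64)


_WSHED = 0
_INIT = -1
_MASK = -2
_FICT = -1  # fictitious queue separator (flat index sentinel)


def watershed(img: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Immersion watershed with explicit divide lines (Vincent-Soille).

    Floods gray levels bottom-up from the regional minima of ``img``;
    returns a label image where 0 marks watershed-line pixels and each
    positive label is one connected catchment basin (one per
    regional-minimum component).  Pixels are processed in raster order
    within each gray level and the flooding queue is FIFO, so the result is
    bit-for-bit reproducible.
    """
    img = _check_image(img)
    if img.min() == img.max():
        return np.ones(img.shape, dtype=np.int32)

    from collections import deque

    h, w = img.shape
    wide = w + 2
    # pad with a sentinel level so neighbor access never bounds-checks;
    # padded pixels stay INIT and are dropped at the end
    vals = np.full((h + 2, w + 2), np.iinfo(np.int64).max, dtype=np.int64)
    vals[1:-1, 1:-1] = img
    flat = vals.ravel()
    lab = np.full(flat.size, _INIT, dtype=np.int32)
    dist = np.zeros(flat.size, dtype=np.int32)

    if connectivity == 8:
        offsets = (-wide - 1, -wide, -wide + 1, -1, 1, wide - 1, wide, wide + 1)
    else:
        offsets = (-wide, -1, 1, wide)

    interior = (np.arange(1, h + 1)[:, None] * wide + np.arange(1, w + 1)).ravel()
    order = interior[np.argsort(flat[interior], kind="stable")]
    levels = flat[order]
    starts = np.searchsorted(levels, np.unique(levels), side="left")
    bounds = list(starts) + [order.size]

    fifo: deque[int] = deque()
    curlab = 0
    for li in range(len(bounds) - 1):
        pixels = order[bounds[li]:bounds[li + 1]]
        # mask the level; queue pixels adjacent to an existing basin/line
        lab[pixels] = _MASK
        for p in pixels:
            for off in offsets:
                if lab[p + off] >= _WSHED:
                    dist[p] = 1
                    fifo.append(p)
                    break
        curdist = 1
        fifo.append(_FICT)
        while True:
            p = fifo.popleft()
            if p == _FICT:
                if not fifo:
                    break
                fifo.append(_FICT)
                curdist += 1
                p = fifo.popleft()
            for off in offsets:
                q = p + off
                lq = lab[q]
                if dist[q] < curdist and lq >= _WSHED:
                    if lq > 0:
                        lp = lab[p]
                        if lp == _MASK or lp == _WSHED:
                            lab[p] = lq
                        elif lp != lq:
                            lab[p] = _WSHED
                    elif lab[p] == _MASK:
                        lab[p] = _WSHED
                elif lq == _MASK and dist[q] == 0:
                    dist[q] = curdist + 1
                    fifo.append(q)
        # remaining masked pixels are new minima: one fresh label per component
        dist[pixels] = 0
        for p in pixels:
            if lab[p] == _MASK:
                curlab += 1
                lab[p] = curlab
                fifo.append(p)
                while fifo:
                    r = fifo.popleft()
                    for off in offsets:
                        q = r + off
                        if lab[q] == _MASK:
                            lab[q] = curlab
                            fifo.append(q)

    return lab.reshape(h + 2, w + 2)[1:-1, 1:-1].copy()


# ---------------------------------------------------------------------------
# Binary cleaning helpers
# ---------------------------------------------------------------------------

def area_filter(mask: np.ndarray, min_px: int, max_px: int, connectivity: int = 8) -> np.ndarray:
    """Keep connected components whose area a satisfies min_px <= a <= max_px."""
    if min_px > max_px:
        raise ValueError(f"min_px ({min_px}) must not exceed max_px ({max_px})")
    mask = _check_image(mask).astype(bool)
    structure = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels, n = ndi.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask)
    areas = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = (areas[1:] >= min_px) & (areas[1:] <= max_px)
    return keep[labels]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Close holes: background components not connected to the border
    (4-connected background) become foreground."""
    mask = _check_image(mask).astype(bool)
    return ndi.binary_fill_holes(mask, structure=_STRUCT4)


def remove_border_objects(mask: np.ndarray) -> np.ndarray:
    """Delete every foreground component touching an image border.

    Implemented as binary reconstruction from a border marker followed by
    subtraction.
    """
    mask = _check_image(mask).astype(bool)
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = binary_reconstruct(border & mask, mask)
    return mask & ~touching
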