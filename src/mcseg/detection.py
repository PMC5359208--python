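"""Four-stage multiscale morphological microcalcification detector.

Produces a binary microcalcification "map" from an 8-bit mammogram ROI:

1. Clip dark gray levels (saturating down-shift then up-shift by ``diff``),
   removing low-intensity variance that could mimic small bright spots.
2. Build a 3-level morphological pyramid (closing-opening filter + stride-2
   sampling per level) and apply the bright-spot residue detector

       T = I - min(opening(closing(I)), I)

   with a 3x3 square at pyramid levels 2 and 3; threshold the residues at
   ``th`` and restore each mask to full size by block replication.
3. Extract all bright plateaus of the clipped image as the support of the
   h-maxima residue (extended maxima, height ``h``), then discard regions
   through which a directional chord longer than ``n_pxls`` pixels can be
   drawn (erosion by length-(n_pxls+1) lines in four orientations, OR of the
   results as reconstruction marker, subtraction of the reconstruction).
4. Reconstruct, per pyramid level, the bright regions hit by the level's
   detection signal; OR the two reconstructions into the map; then clean:
   remove border-touching components, keep components with area in
   [min_pxls, max_pxls], and close holes.

Default parameters are the values established on the 20-ROI training set
(diff=21, th=4, h=5, n_pxls=50, min_pxls=10, max_pxls=70).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from . import morphology as mm

__all__ = ["DetectionParams", "stage1_clip", "build_pyramid", "detect_level",
           "upsample_mask", "multiscale_signals", "bright_regions",
           "build_map", "detect"]


@dataclass(frozen=True)
class DetectionParams:
    """Tuning parameters of the morphological detector.

    diff:     gray-level clip applied in stage 1.
    th:       threshold on the stage-2 residue at each pyramid level.
    h:        height of the extended-maximum transform in stage 3.
    n_pxls:   longest admissible directional chord through a bright region;
              regions with a longer horizontal/vertical/diagonal chord are
              removed as non-lesion structures.
    min_pxls, max_pxls: admissible component area (px) of the final map.
    pyramid_levels: fixed at 3.
    """

    diff: int = 21
    th: int = 4
    h: int = 5
    n_pxls: int = 50
    min_pxls: int = 10
    max_pxls: int = 70
    pyramid_levels: int = 3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{f.name} must be a positive integer, got {v!r}")
        if self.min_pxls > self.max_pxls:
            raise ValueError("min_pxls must not exceed max_pxls")
        if self.pyramid_levels != 3:
            raise ValueError("pyramid_levels is fixed at 3")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "DetectionParams":
        """Build params from a config mapping; unknown keys are rejected,
        absent keys fall back to the defaults."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown detection parameter(s): {sorted(unknown)}")
        return cls(**{k: int(v) for k, v in mapping.items()})


def stage1_clip(img: np.ndarray, diff: int = 21) -> np.ndarray:
    """Saturating shift down then up by ``diff`` gray levels.

    Closed form: pointwise ``max(img, diff)``.  All variance below ``diff``
    is flattened, so dark-region specks cannot trigger the detector.
    """
    if not 0 < diff < 255:
        raise ValueError(f"diff must be in (0, 255), got {diff}")
    img = np.asarray(img)
    return np.maximum(img, diff).astype(img.dtype)


def build_pyramid(img: np.ndarray) -> list[np.ndarray]:
    """3-level morphological pyramid.

    Level 1 is the input; each further level is the closing-opening filter
    of the previous one sampled at every second pixel (even indices).
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError(f"image must be 2-D and at least 8x8, got shape {img.shape}")
    levels = [img]
    for _ in range(2):
        levels.append(mm.co_filter(levels[-1])[::2, ::2])
    return levels


def detect_level(img: np.ndarray, th: int = 4) -> np.ndarray:
    """Bright-spot residue detector at one pyramid level.

    T = I - min(opening(closing(I)), I) with the 3x3 square; the pointwise
    min keeps the residue non-negative.  Returns threshold(T, th).
    """
    img = np.asarray(img)
    se = mm.square3()
    t = img.astype(np.int64) - np.minimum(mm.opening(mm.closing(img, se), se), img)
    return mm.threshold(t, th)


def upsample_mask(mask: np.ndarray, scale: int, target_shape: tuple[int, int]) -> np.ndarray:
    """Restore a pyramid-level mask to full size by block replication.

    Every pixel becomes a scale x scale block; the result is cropped (and if
    short, padded with background) to ``target_shape``, anchored at (0, 0).
    """
    if scale not in (2, 4):
        raise ValueError(f"scale must be 2 or 4, got {scale}")
    mask = np.asarray(mask).astype(bool)
    th_, tw = target_shape
    if mask.shape[0] * scale < th_ - (scale - 1) or mask.shape[1] * scale < tw - (scale - 1):
        raise ValueError(
            f"mask of shape {mask.shape} at scale {scale} cannot cover target {target_shape}")
    big = np.kron(mask, np.ones((scale, scale), dtype=bool))
    out = np.zeros(target_shape, dtype=bool)
    h = min(th_, big.shape[0])
    w = min(tw, big.shape[1])
    out[:h, :w] = big[:h, :w]
    return out


def multiscale_signals(
    img2: np.ndarray, p: DetectionParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Detection signals at pyramid levels 2 and 3, restored to full size.

    Returns (level-2 mask, level-3 mask, their OR).  The level masks are
    kept separate because stage 4 reconstructs bright regions per level.
    """
    p = p or DetectionParams()
    levels = build_pyramid(img2)
    sig2 = upsample_mask(detect_level(levels[1], p.th), 2, img2.shape)
    sig3 = upsample_mask(detect_level(levels[2], p.th), 4, img2.shape)
    return sig2, sig3, sig2 | sig3


def bright_regions(img2: np.ndarray, h: int = 5, n_pxls: int = 50) -> np.ndarray:
    """Bright plateaus of the clipped image, with elongated regions removed.

    The support of the h-maxima residue (extended maxima) contains both
    microcalcifications and larger bright structures.  Any region inside
    which a horizontal, vertical or diagonal chord strictly longer than
    ``n_pxls`` can be drawn is identified by erosion with length-(n_pxls+1)
    linear structuring elements (OR of the four directions), reconstructed,
    and subtracted.
    """
    if n_pxls < 1:
        raise ValueError(f"n_pxls must be >= 1, got {n_pxls}")
    emax = mm.threshold(mm.h_convexity(img2, h), 1)
    length = n_pxls + 1 if (n_pxls + 1) % 2 == 1 else n_pxls + 2
    emax_u8 = emax.astype(np.uint8) * 255
    marker = np.zeros_like(emax)
    for orientation in ("horizontal", "vertical", "diag_left", "diag_right"):
        se = mm.line_se(orientation, length)
        marker |= mm.erode(emax_u8, se) > 0
    large = mm.binary_reconstruct(marker, emax)
    return emax & ~large


def build_map(
    bright: np.ndarray,
    sig2: np.ndarray,
    sig3: np.ndarray,
    p: DetectionParams | None = None,
) -> np.ndarray:
    """Stage 4: reconstruct detected bright regions per level, OR, clean.

    For each pyramid level the marker is the intersection of the bright
    regions with that level's detection signal; reconstruction recovers the
    full bright components hit.  Cleaning then removes border-touching
    components, keeps areas in [min_pxls, max_pxls], and closes holes.
    """
    p = p or DetectionParams()
    bright = np.asarray(bright).astype(bool)
    sig2 = np.asarray(sig2).astype(bool)
    sig3 = np.asarray(sig3).astype(bool)
    if not (bright.shape == sig2.shape == sig3.shape):
        raise ValueError("bright and signal masks must share a shape")
    rec2 = mm.binary_reconstruct(bright & sig2, bright)
    rec3 = mm.binary_reconstruct(bright & sig3, bright)
    mc_map = rec2 | rec3
    mc_map = mm.remove_border_objects(mc_map)
    mc_map = mm.area_filter(mc_map, p.min_pxls, p.max_pxls)
    return mm.fill_holes(mc_map)


def detect(img: np.ndarray, p: DetectionParams | None = None) -> np.ndarray:
    """Run all four detection stages; returns the microcalcification map."""
    p = p or DetectionParams()
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("input must be a single-channel 2-D image")
    img2 = stage1_clip(img, p.diff)
    sig2, sig3, _ = multiscale_signals(img2, p)
    bright = bright_regions(img2, p.h, p.n_pxls)
    return build_map(bright, sig2, sig3, p)
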