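"""Synthetic mammogram-ROI phantoms with pixel-exact ground truth.

Real microcalcifications are tiny (0.1–1.0 mm, ~2–20 px at a 50 µm pixel
pitch, average 0.3 mm), low-contrast bright spots on a smooth textured
background.  Benign lesions tend to be larger, few (<4–5 per cluster area)
and spread out; malignant ones are small, numerous (>5 in ~1 cm²) and
densely clustered.  The generator emulates exactly these descriptive
statistics — it is not a physical breast-tissue simulation:

* background: flat, linear gradient, or a smooth low-frequency random field;
* lesions: isotropic flattened super-Gaussian bright blobs
  (``c * exp(-(r^2 / 2 sigma^2)^p)``, default order p = 2).  Calcium
  deposits are sharply bounded and near-uniform in brightness, so a
  flat-topped profile with a smooth rolloff is closer to the real signal
  than a pure Gaussian peak; order 1 recovers the Gaussian.  The truth mask
  of a blob is its half-peak support, so a "diameter" is the full width at
  half maximum in pixels;
* optional elongated bright distractor bands whose directional chords exceed
  the detector's ``n_pxls`` limit, exercising the chord-removal rule;
* additive Gaussian noise, with the final image clipped to 8-bit range.

Every output is a deterministic function of (spec, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import convex_hull_image

__all__ = ["PhantomSpec", "PhantomTruth", "PlacementError",
           "easy_spec", "generate", "sweep"]

#: pixel pitch assumed for mm <-> px conversion (µm per pixel)
PIXEL_PITCH_UM = 50.0

def _sigma_for_fwhm(d: float, order: float) -> float:
    """Scale parameter of a super-Gaussian with full width at half maximum d."""
    return (d / 2.0) / (np.sqrt(2.0) * np.log(2.0) ** (1.0 / (2.0 * order)))


class PlacementError(RuntimeError):
    """Raised when lesions cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation recipe for one synthetic ROI.

    diameter_range is the truth (half-peak) diameter in px; at a 50 µm
    pitch the default 2–20 px maps to 0.1–1.0 mm.  contrast_range is the
    blob peak height above the local background in gray levels.
    """

    width: int = 512
    height: int = 512
    lesion_type: str = "benign"  # benign | malignant | none
    n_calcs: int | None = None
    diameter_range: tuple[float, float] = (2.0, 20.0)
    contrast_range: tuple[float, float] = (8.0, 40.0)
    cluster_radius: float | None = None
    background: str = "textured"  # flat | gradient | textured
    noise_sigma: float = 2.0
    n_distractors: int = 0
    profile_order: float = 2.0  # super-Gaussian exponent; 1 = Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_type not in ("benign", "malignant", "none"):
            raise ValueError(f"unknown lesion_type {self.lesion_type!r}")
        if self.background not in ("flat", "gradient", "textured"):
            raise ValueError(f"unknown background {self.background!r}")
        lo, hi = self.diameter_range
        if not (0 < lo <= hi):
            raise ValueError("diameter_range must be positive and ordered")
        lo, hi = self.contrast_range
        if not (0 < lo <= hi):
            raise ValueError("contrast_range must be positive and ordered")
        if self.n_calcs is None:
            object.__setattr__(
                self, "n_calcs",
                {"benign": 4, "malignant": 8, "none": 0}[self.lesion_type])
        if self.n_calcs < 0:
            raise ValueError("n_calcs must be >= 0")
        if self.profile_order < 1.0:
            raise ValueError("profile_order must be >= 1")
        if self.lesion_type == "malignant" and self.n_calcs <= 5:
            raise ValueError("malignant phantoms are numerous: n_calcs must exceed 5")
        if self.lesion_type == "benign" and self.n_calcs > 5:
            raise ValueError("benign phantoms are sparse: n_calcs must be <= 5")
        if self.cluster_radius is None:
            # malignant clusters fit ~1 cm^2 (200x200 px at 50 um); benign spread out
            r = 80.0 if self.lesion_type == "malignant" else min(self.width, self.height) / 2.5
            object.__setattr__(self, "cluster_radius", r)


@dataclass(frozen=True)
class PhantomTruth:
    """A generated ROI with its ground truth."""

    image: np.ndarray          # uint8
    calc_mask: np.ndarray      # bool, union of per-lesion half-peak supports
    calc_labels: np.ndarray    # int, one label per lesion
    gta: np.ndarray            # bool, convex hull of lesions with margin
    per_object: pd.DataFrame = field(repr=False)
    spec: PhantomSpec = field(repr=False, default=None)


def easy_spec(seed: int = 0, size: int = 256) -> PhantomSpec:
    """A favourable-condition phantom for end-to-end recovery checks.

    High contrast (>= 20), low noise, no distractors, and truth diameters
    of 8.2–9.2 px so both the half-peak areas (~53–66 px) and the detector's
    top-h caps (>= ~17 px analytically) lie within the [10, 70] px area
    filter with margin for discretization.
    """
    return PhantomSpec(
        width=size, height=size,
        lesion_type="benign", n_calcs=5,
        diameter_range=(8.2, 9.2),
        contrast_range=(20.0, 24.0),
        background="textured",
        noise_sigma=1.0,
        n_distractors=0,
        seed=seed,
    )


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    if spec.background == "flat":
        return np.full((h, w), 120.0)
    if spec.background == "gradient":
        ramp = np.linspace(70.0, 150.0, w)
        return np.tile(ramp, (h, 1))
    # low-frequency field: gentle enough that the background rise across one
    # lesion (a few px) stays well below the detector's h=5 dome height
    field_ = rng.normal(size=(h, w))
    field_ = ndi.gaussian_filter(field_, sigma=min(h, w) / 6.0, mode="nearest")
    lo, hi = field_.min(), field_.max()
    if hi - lo < 1e-9:
        return np.full((h, w), 120.0)
    return 100.0 + (field_ - lo) / (hi - lo) * 40.0


def _place_centers(spec: PhantomSpec, diameters: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    margin = float(diameters.max()) * 1.5 + 8.0
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError(f"ROI {h}x{w} too small for lesions of this size")
    if spec.lesion_type == "malignant":
        lo_y, hi_y = margin + spec.cluster_radius, h - margin - spec.cluster_radius
        lo_x, hi_x = margin + spec.cluster_radius, w - margin - spec.cluster_radius
        if hi_y <= lo_y or hi_x <= lo_x:
            raise PlacementError(f"cluster radius {spec.cluster_radius} does not fit "
                                 f"inside a {h}x{w} ROI")
        cy = rng.uniform(lo_y, hi_y)
        cx = rng.uniform(lo_x, hi_x)
    centers: list[tuple[float, float]] = []
    for i, d in enumerate(diameters):
        for _ in range(400):
            if spec.lesion_type == "malignant":
                ang = rng.uniform(0, 2 * np.pi)
                rad = spec.cluster_radius * np.sqrt(rng.uniform())
                y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            else:
                y = rng.uniform(margin, h - margin)
                x = rng.uniform(margin, w - margin)
            if not (margin <= y <= h - margin and margin <= x <= w - margin):
                continue
            sep_ok = all(
                np.hypot(y - yc, x - xc) >= (d + diameters[j]) * 1.2 + 6.0
                for j, (yc, xc) in enumerate(centers)
            )
            if sep_ok:
                centers.append((y, x))
                break
        else:
            raise PlacementError(
                f"could not place lesion {i} without overlap after 400 tries")
    return np.asarray(centers).reshape(-1, 2)


def _add_distractors(img: np.ndarray, n: int, centers: np.ndarray,
                     diameters: np.ndarray, rng: np.random.Generator) -> None:
    h, w = img.shape
    for _ in range(n):
        for _ in range(200):
            horizontal = rng.uniform() < 0.5
            length, thick = int(rng.integers(70, 110)), int(rng.integers(5, 10))
            bh, bw = (thick, length) if horizontal else (length, thick)
            if h - bh - 2 <= 2 or w - bw - 2 <= 2:
                break
            r0 = int(rng.integers(2, h - bh - 2))
            c0 = int(rng.integers(2, w - bw - 2))
            box_cy, box_cx = r0 + bh / 2, c0 + bw / 2
            clear = all(
                np.hypot(box_cy - yc, box_cx - xc) > max(bh, bw) / 2 + d + 12
                for (yc, xc), d in zip(centers, diameters)
            ) if len(centers) else True
            if clear:
                img[r0:r0 + bh, c0:c0 + bw] += 30.0
                break


def generate(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom ROI and its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = _background(spec, rng)

    n = spec.n_calcs
    diameters = rng.uniform(*spec.diameter_range, size=n)
    contrasts = rng.uniform(*spec.contrast_range, size=n)
    centers = _place_centers(spec, diameters, rng) if n else np.empty((0, 2))

    calc_labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    for i in range(n):
        y0, x0 = centers[i]
        sigma = _sigma_for_fwhm(diameters[i], spec.profile_order)
        r2 = (yy - y0) ** 2 + (xx - x0) ** 2
        blob = contrasts[i] * np.exp(-((r2 / (2.0 * sigma ** 2)) ** spec.profile_order))
        img += blob
        support = blob >= contrasts[i] / 2.0
        calc_labels[support] = i + 1
        rows.append({
            "label": i + 1,
            "row": float(y0),
            "col": float(x0),
            "diameter_px": float(diameters[i]),
            "diameter_mm": float(diameters[i] * PIXEL_PITCH_UM / 1000.0),
            "contrast": float(contrasts[i]),
            "area_px": int(support.sum()),
        })

    _add_distractors(img, spec.n_distractors, centers, diameters, rng)

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=(h, w))
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    calc_mask = calc_labels > 0
    if calc_mask.any():
        gta = ndi.binary_dilation(convex_hull_image(calc_mask),
                                  structure=np.ones((3, 3), bool), iterations=10)
    else:
        gta = np.zeros((h, w), dtype=bool)

    per_object = pd.DataFrame(
        rows, columns=["label", "row", "col", "diameter_px", "diameter_mm",
                       "contrast", "area_px"])
    return PhantomTruth(image=image, calc_mask=calc_mask, calc_labels=calc_labels,
                        gta=gta, per_object=per_object, spec=spec)


def sweep(base: PhantomSpec, grid: dict[str, list]) -> list[PhantomTruth]:
    """Cartesian sweep over spec fields; cell i runs at seed base.seed + i.

    ``grid`` maps PhantomSpec field names (e.g. contrast_range,
    diameter_range, noise_sigma) to lists of values.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("sweep grid must be non-empty")
    keys = sorted(grid)
    out = []
    for i, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        cell = replace(base, **dict(zip(keys, combo)), seed=base.seed + i)
        out.append(generate(cell))
    return out
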