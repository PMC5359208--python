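"""Image/mask readers and writers plus run configuration.

Accepted raster formats are 8-bit single-channel PNG and PGM (P5).  Color
or deeper inputs are rejected outright rather than silently converted, so a
run never works on data it was not designed for.  Masks are stored with
255 = foreground on disk and booleans in memory; round trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .detection import DetectionParams

__all__ = ["ImageFormatError", "RunConfig", "load_config",
           "read_image", "read_mask", "write_image", "write_mask",
           "write_overlay"]


class ImageFormatError(ValueError):
    """Unsupported raster format (wrong bit depth, channels, or missing file)."""


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit single-channel PNG/PGM as a uint8 array."""
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"{path}: file not found")
    try:
        img = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ImageFormatError(f"{path}: unreadable image ({exc})") from exc
    if img.ndim != 2:
        raise ImageFormatError(
            f"{path}: expected a single-channel image, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise ImageFormatError(
            f"{path}: expected 8-bit data, got dtype {img.dtype}")
    return img


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (any nonzero pixel is foreground)."""
    return read_image(path) > 0


def write_image(path: str | Path, img: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_image(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255)


def write_overlay(path: str | Path, img: np.ndarray, lines: np.ndarray) -> None:
    """Write an RGB overlay with watershed-line pixels drawn in red."""
    img = np.asarray(img, dtype=np.uint8)
    lines = np.asarray(lines, dtype=bool)
    if img.shape != lines.shape:
        raise ValueError("image and line mask shapes differ")
    rgb = np.stack([img, img, img], axis=-1)
    rgb[lines] = (255, 0, 0)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for the command-line surface."""

    params: DetectionParams = field(default_factory=DetectionParams)
    tau: float = 0.5
    connectivity: int = 8
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


_TOP_KEYS = {"params", "tau", "connectivity", "seed", "log_level"}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected.

    Detection parameters live under ``params`` with keys named diff, th, h,
    n_pxls, min_pxls, max_pxls; absent keys take the established defaults.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    params = DetectionParams.from_mapping(data.get("params", {}))
    return RunConfig(
        params=params,
        tau=float(data.get("tau", 0.5)),
        connectivity=int(data.get("connectivity", 8)),
        seed=int(data.get("seed", 0)),
        log_level=str(data.get("log_level", "INFO")),
    )
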