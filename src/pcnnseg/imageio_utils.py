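"""Raster I/O and run configuration.

Coordinate convention: row-major, 0-based, (row, col).  Masks are written
as 0/255 8-bit PNG with 255 = positive.  Grayscale inputs (PNG/TIFF/PGM)
are normalized to [0, 1] by the container maximum (255 or 65535).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .autoparams import normalize_image

__all__ = [
    "read_gray_image",
    "read_mask",
    "write_gray_image",
    "write_mask",
    "write_label_map",
    "write_rgb",
    "RunConfig",
]


def read_gray_image(path, luminance: bool = False) -> np.ndarray:
    """Read a single-channel image and normalize it to [0, 1].

    Multi-channel files are rejected unless ``luminance=True``, in which
    case they are converted with the Rec. 601 luma weights before
    normalization.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if not luminance:
            raise ValueError(f"{path}: multi-channel image; pass luminance=True "
                             "(--luminance) to convert to grayscale")
        rgb = arr[..., :3].astype(float)
        gray = rgb @ np.array([0.299, 0.587, 0.114])
        return normalize_image(np.clip(gray, 0, np.iinfo(arr.dtype).max
                                       if np.issubdtype(arr.dtype, np.integer) else 1.0)
                               .astype(arr.dtype))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return normalize_image(arr)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 binary mask PNG as a boolean array."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (arr.max() / 2 if arr.max() > 1 else 0)


def write_gray_image(path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write a [0, 1] float image as 8- or 16-bit grayscale."""
    image = np.asarray(image, dtype=float)
    if bit_depth == 8:
        iio.imwrite(path, np.clip(np.round(image * 255), 0, 255).astype(np.uint8))
    elif bit_depth == 16:
        iio.imwrite(path, np.clip(np.round(image * 65535), 0, 65535).astype(np.uint16))
    else:
        raise ValueError("bit_depth must be 8 or 16")


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask).astype(np.uint8) * 255))


def write_label_map(path, labels: np.ndarray) -> None:
    """Write integer group labels as a 16-bit PNG."""
    iio.imwrite(path, np.asarray(labels).astype(np.uint16))


def write_rgb(path, rgb: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(rgb, dtype=np.uint8))


@dataclass
class RunConfig:
    """Fully serializable description of one segmentation run.

    A run reproduces bit-identically from its saved config (all models are
    deterministic; the only randomness in the package flows through the
    explicit seeds).
    """

    model: str = "spcnn"
    nmax: int = 100
    st: float | None = None
    w: float | None = None
    phi: float | None = None
    seed: int = 0
    polarity: str = "bright"
    iou_mode: str = "binary"
    sprime: float | None = None
    params: dict | None = None  # explicit ModelParams overrides auto setting

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        text = source if str(source).lstrip().startswith("{") else Path(source).read_text()
        d = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    def digest(self) -> str:
        """Stable hash of the canonical JSON form, for artifact provenance."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
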