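"""Lossless 8-bit PNG/BMP I/O for grayscale images and label masks.

Images travel as floats in [0, 1] in memory and 8-bit grayscale on disk;
masks carry literal label values (0..255, no palette) and round-trip
exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]

_ACCEPTED_SUFFIXES = {".png", ".bmp"}


def _open_8bit(path: str | Path) -> Image.Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        img = Image.open(path)
    except UnidentifiedImageError as exc:
        raise ValueError(f"not a readable image file: {path}") from exc
    if img.mode in ("I", "I;16", "I;16B", "F"):
        raise ValueError(f"{path}: 16-bit/float images are not supported; provide 8-bit grayscale")
    if img.mode != "L":
        img = img.convert("L")
    return img


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/BMP as a float32 array in [0, 1]."""
    arr = np.asarray(_open_8bit(path), dtype=np.float32) / 255.0
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 8-bit grayscale."""
    path = Path(path)
    if path.suffix.lower() not in _ACCEPTED_SUFFIXES:
        raise ValueError(f"unsupported image suffix {path.suffix!r}; use .png or .bmp")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    Image.fromarray((image * 255.0).round().astype(np.uint8), mode="L").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit label mask with literal values (no rescaling)."""
    return np.asarray(_open_8bit(path), dtype=np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write an integer label mask losslessly as 8-bit grayscale."""
    path = Path(path)
    if path.suffix.lower() not in _ACCEPTED_SUFFIXES:
        raise ValueError(f"unsupported mask suffix {path.suffix!r}; use .png or .bmp")
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2D mask, got shape {mask.shape}")
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("mask labels must fit in uint8")
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)
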