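"""Euclidean distance-transform features for the second cascade stage.

Each lower disc instance yields a map that is zero on the disc and grows
outward with exact Euclidean distance; normalized maps are stacked with
the raw image into the 3-channel input (image, distance-to-disc-2,
distance-to-disc-3) that lets the upper-disc network exploit relative
position.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "distance_transform",
    "normalize_distance",
    "fuse_channels",
    "composite_rgb",
]


def distance_transform(source: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance (pixel centers) to the nearest source pixel.

    Zero on the source; raises on an empty source, where the distance is
    undefined.
    """
    source = np.asarray(source).astype(bool)
    if source.ndim != 2:
        raise ValueError(f"expected a 2D mask, got shape {source.shape}")
    if not source.any():
        raise ValueError("source region is empty; distance transform undefined")
    # EDT of the complement: distance from each pixel to the nearest
    # foreground pixel of `source`.
    return ndimage.distance_transform_edt(~source)


def normalize_distance(dist: np.ndarray, scale: float) -> np.ndarray:
    """Map distances into [0, 1] as ``min(d / scale, 1)``."""
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    return np.minimum(np.asarray(dist, dtype=np.float64) / scale, 1.0)


def fuse_channels(
    image: np.ndarray, d2: np.ndarray, d3: np.ndarray, scale: float | None = None
) -> np.ndarray:
    """Stack (image, normalized d2, normalized d3) into a (3, H, W) input.

    ``scale`` defaults to the image diagonal so features stay in [0, 1]
    regardless of image size.
    """
    image = np.asarray(image, dtype=np.float64)
    d2 = np.asarray(d2, dtype=np.float64)
    d3 = np.asarray(d3, dtype=np.float64)
    if not (image.shape == d2.shape == d3.shape):
        raise ValueError(f"shape mismatch: {image.shape}, {d2.shape}, {d3.shape}")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must be normalized to [0, 1]")
    if scale is None:
        scale = float(np.hypot(*image.shape))
    return np.stack([image, normalize_distance(d2, scale), normalize_distance(d3, scale)]).astype(
        np.float32
    )


def composite_rgb(fused: np.ndarray) -> np.ndarray:
    """Debug view: the fused channels as an (H, W, 3) uint8 RGB image."""
    fused = np.asarray(fused)
    if fused.ndim != 3 or fused.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) stack, got shape {fused.shape}")
    return np.clip(np.moveaxis(fused, 0, -1) * 255.0, 0, 255).round().astype(np.uint8)
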