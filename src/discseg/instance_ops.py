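"""Connected-component instance labeling and lower-disc cropping.

Instances of a binary mask are labeled as maximal connected foreground
regions and then renumbered 1..K top to bottom by centroid row, matching
the convention that disc 1 is the uppermost target and disc 3 the lowest.
The crop helpers cut the window around instances 2 and 3 (the lower disc
pair) used to train the first cascade stage.

All coordinates are 0-based, row-major; windows are half-open ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CropWindow",
    "connected_components",
    "relabel_top_to_bottom",
    "count_instances",
    "lower_disc_crop",
    "apply_crop",
    "paste_back",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class CropWindow:
    """Half-open pixel window [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ValueError(f"invalid row range [{self.row_start}, {self.row_end})")
        if not (0 <= self.col_start < self.col_end):
            raise ValueError(f"invalid col range [{self.col_start}, {self.col_end})")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_end - self.row_start, self.col_end - self.col_start)


def connected_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected foreground regions, ordered top to bottom.

    Returns an integer mask with labels exactly {0} ∪ {1..K}; label k's
    centroid row is <= label k+1's (strict, with the documented tie-break).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2D mask, got shape {mask.shape}")
    raw, _ = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    return relabel_top_to_bottom(raw)


def _sort_keys(labels: np.ndarray, values: np.ndarray) -> list[tuple]:
    """Per-instance (centroid_row, centroid_col, first_flat_index) keys."""
    keys = []
    for val in values:
        rows, cols = np.nonzero(labels == val)
        keys.append((rows.mean(), cols.mean(), rows[0] * labels.shape[1] + cols[0]))
    return keys


def relabel_top_to_bottom(labels: np.ndarray) -> np.ndarray:
    """Permute instance identities so centroid rows increase with label value.

    Ties on centroid row break by smaller centroid column, then by smaller
    row-major first-pixel index. Idempotent; pixel counts are conserved.
    """
    labels = np.asarray(labels)
    values = np.unique(labels)
    values = values[values > 0]
    if values.size == 0:
        return np.zeros_like(labels, dtype=np.int32)
    keys = _sort_keys(labels, values)
    ranked = sorted(range(len(values)), key=lambda i: keys[i])
    out = np.zeros_like(labels, dtype=np.int32)
    for new_label, idx in enumerate(ranked, start=1):
        out[labels == values[idx]] = new_label
    return out


def count_instances(mask: np.ndarray, connectivity: int = 8) -> int:
    """Number of connected foreground regions."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    _, n = ndimage.label(np.asarray(mask).astype(bool), structure=_STRUCTURES[connectivity])
    return int(n)


def lower_disc_crop(labels: np.ndarray, margin_frac: float = 0.25) -> CropWindow:
    """Window around instances 2 and 3, expanded by a fractional margin.

    The tight half-open bounding box of the union of instances 2 and 3 is
    expanded on each side by ``margin_frac`` of its height (rows) and width
    (cols), truncated to integers and clipped to the image bounds.
    """
    labels = np.asarray(labels)
    lower = (labels == 2) | (labels == 3)
    if not (labels == 2).any() or not (labels == 3).any():
        raise ValueError("labels must contain instances 2 and 3 to form the lower-disc crop")
    rows, cols = np.nonzero(lower)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    mr = margin_frac * (r1 - r0)
    mc = margin_frac * (c1 - c0)
    h, w = labels.shape
    return CropWindow(
        row_start=max(0, int(np.floor(r0 - mr))),
        row_end=min(h, int(np.floor(r1 + mr))),
        col_start=max(0, int(np.floor(c0 - mc))),
        col_end=min(w, int(np.floor(c1 + mc))),
    )


def apply_crop(array: np.ndarray, window: CropWindow) -> np.ndarray:
    """Extract the window from a 2D image or mask."""
    array = np.asarray(array)
    h, w = array.shape[:2]
    if window.row_end > h or window.col_end > w:
        raise ValueError(f"window {window} exceeds array shape {array.shape}")
    return array[window.row_start : window.row_end, window.col_start : window.col_end].copy()


def paste_back(cropped: np.ndarray, window: CropWindow, canvas_size: tuple[int, int]) -> np.ndarray:
    """Place a cropped array back onto a zero canvas of the original size."""
    cropped = np.asarray(cropped)
    if cropped.shape[:2] != window.shape:
        raise ValueError(f"cropped shape {cropped.shape} does not match window {window.shape}")
    h, w = canvas_size
    if window.row_end > h or window.col_end > w:
        raise ValueError(f"window {window} exceeds canvas {canvas_size}")
    canvas = np.zeros((h, w) + cropped.shape[2:], dtype=cropped.dtype)
    canvas[window.row_start : window.row_end, window.col_start : window.col_end] = cropped
    return canvas
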