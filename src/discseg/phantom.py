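"""Synthetic spine phantoms: images plus ground-truth disc instance masks.

Each phantom is a roughly vertical, gently curved column of bright
vertebral-body blobs (rounded rectangles) separated by brighter elliptical
disc blobs.  Only three designated discs are foreground in the reference
mask — one isolated upper disc and two adjacent lower discs — while the
remaining discs act as look-alike distractors that appear in the image but
not in the mask.  Additive Gaussian noise and a smooth polynomial bias
field make the intensities non-trivial.

The generator is fully deterministic per seed, so datasets regenerate
bit-identically from a manifest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import fileio

__all__ = ["PhantomParams", "PhantomSample", "generate_sample", "generate_dataset", "load_dataset"]

_MARGIN_FRAC = 0.08
_VERT_HALF_HEIGHT = 0.24  # of the column pitch
_VERT_HALF_WIDTH = 0.42
_ROW_JITTER = 0.02
_BACKGROUND = 0.2
_VERTEBRA_INTENSITY = 0.5
_DISC_INTENSITY = 0.85


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and randomness knobs of one phantom."""

    image_size: int = 128
    n_vertebrae: int = 6
    n_discs: int = 5
    target_disc_indices: tuple[int, int, int] = (0, 3, 4)
    disc_axis_lengths: tuple[tuple[float, float], tuple[float, float]] | None = None
    column_curvature: float | None = None
    noise_sd: float = 0.03
    bias_amplitude: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_discs != self.n_vertebrae - 1:
            raise ValueError(
                f"discs sit between consecutive vertebrae: expected n_discs == "
                f"n_vertebrae - 1, got {self.n_discs} vs {self.n_vertebrae}"
            )
        idx = self.target_disc_indices
        if len(idx) != 3 or not all(0 <= i < self.n_discs for i in idx):
            raise ValueError(f"target_disc_indices must be 3 indices in [0, {self.n_discs}), got {idx}")
        if not (idx[0] < idx[1] < idx[2]):
            raise ValueError(f"target_disc_indices must be strictly increasing, got {idx}")
        if idx[2] != idx[1] + 1:
            raise ValueError(f"the lower two target discs must be consecutive, got {idx}")
        if idx[1] - idx[0] - 1 < 2:
            raise ValueError(
                f"the upper target disc must be separated from the lower pair by >= 2 "
                f"distractor discs, got {idx}"
            )
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd and bias_amplitude must be non-negative")

    @property
    def pitch(self) -> float:
        usable = self.image_size * (1.0 - 2.0 * _MARGIN_FRAC)
        return usable / self.n_vertebrae

    def resolved_disc_axes(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Semi-axis ranges ((a_lo, a_hi), (b_lo, b_hi)) in pixels (a vertical)."""
        if self.disc_axis_lengths is not None:
            return self.disc_axis_lengths
        p = self.pitch
        return ((0.13 * p, 0.18 * p), (0.32 * p, 0.45 * p))

    def resolved_curvature(self) -> float:
        return 0.03 * self.image_size if self.column_curvature is None else self.column_curvature


@dataclass
class PhantomSample:
    """One generated phantom: image in [0, 1], mask with labels {0,1,2,3}."""

    image: np.ndarray
    mask: np.ndarray
    metadata: dict = field(default_factory=dict)


def _ellipse_support(shape, cy, cx, a, b, theta, rows, cols) -> np.ndarray:
    """Pixels inside a rotated ellipse with vertical semi-axis a, horizontal b."""
    dy = rows - cy
    dx = cols - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / b) ** 2 + (v / a) ** 2 <= 1.0


def _superellipse_support(shape, cy, cx, hh, hw, theta, rows, cols) -> np.ndarray:
    """Rounded-rectangle (order-4 superellipse) support."""
    dy = rows - cy
    dx = cols - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return np.abs(u / hw) ** 4 + np.abs(v / hh) ** 4 <= 1.0


def generate_sample(params: PhantomParams) -> PhantomSample:
    """Generate one phantom deterministically from ``params.seed``."""
    params.validate()
    (a_lo, a_hi), (b_lo, b_hi) = params.resolved_disc_axes()
    pitch = params.pitch
    # Disc and flanking vertebra centers sit pitch/2 apart; their vertical
    # half-extents plus jitter must fit in that gap or blobs overlap.
    max_half_extent = a_hi + _VERT_HALF_HEIGHT * 1.05 * pitch + 2 * _ROW_JITTER * pitch
    if max_half_extent >= 0.5 * pitch:
        raise ValueError(
            f"geometry infeasible: disc semi-axis up to {a_hi:.2f}px plus vertebra "
            f"half-height exceeds the column pitch {pitch:.2f}px; shrink "
            f"disc_axis_lengths or the element count"
        )

    rng = np.random.default_rng(params.seed)
    size = params.image_size
    margin = _MARGIN_FRAC * size
    usable = size - 2 * margin
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)

    curv = params.resolved_curvature()
    phase = rng.uniform(-0.5, 0.5)
    cx0 = size / 2.0 + rng.uniform(-0.03, 0.03) * size

    def lateral(y: float) -> float:
        return curv * np.sin(np.pi * (y - margin) / usable + phase)

    def tilt(y: float) -> float:
        return float(np.arctan(curv * np.pi / usable * np.cos(np.pi * (y - margin) / usable + phase)))

    image = np.full((size, size), _BACKGROUND, dtype=np.float64)

    for k in range(params.n_vertebrae):
        cy = margin + (k + 0.5) * pitch + rng.uniform(-_ROW_JITTER, _ROW_JITTER) * pitch
        cx = cx0 + lateral(cy) + rng.uniform(-0.02, 0.02) * pitch
        hh = _VERT_HALF_HEIGHT * pitch * rng.uniform(0.95, 1.05)
        hw = _VERT_HALF_WIDTH * pitch * rng.uniform(0.9, 1.1)
        sup = _superellipse_support(image.shape, cy, cx, hh, hw, tilt(cy), rows, cols)
        image[sup] = _VERTEBRA_INTENSITY + rng.uniform(-0.02, 0.02)

    mask = np.zeros((size, size), dtype=np.uint8)
    target_rank = {idx: rank for rank, idx in enumerate(params.target_disc_indices, start=1)}
    disc_supports: dict[int, np.ndarray] = {}
    for j in range(params.n_discs):
        cy = margin + (j + 1) * pitch + rng.uniform(-_ROW_JITTER, _ROW_JITTER) * pitch
        cx = cx0 + lateral(cy) + rng.uniform(-0.02, 0.02) * pitch
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(b_lo, b_hi)
        sup = _ellipse_support(image.shape, cy, cx, a, b, tilt(cy), rows, cols)
        if not sup.any():
            raise ValueError(f"geometry infeasible: disc {j} has no pixel support at this size")
        image[sup] = _DISC_INTENSITY + rng.uniform(-0.02, 0.02)
        disc_supports[j] = sup
        if j in target_rank:
            mask[sup] = target_rank[j]

    clean = image.copy()
    if params.bias_amplitude > 0:
        x = (cols - size / 2.0) / (size / 2.0)
        y = (rows - size / 2.0) / (size / 2.0)
        coeff = rng.uniform(-1.0, 1.0, size=6)
        bias = (
            coeff[0]
            + coeff[1] * x
            + coeff[2] * y
            + coeff[3] * x * y
            + coeff[4] * x**2
            + coeff[5] * y**2
        )
        bias /= max(np.abs(bias).max(), 1e-12)
        image = image + params.bias_amplitude * bias
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    for j, sup in disc_supports.items():
        if j not in target_rank and (mask[sup] > 0).any():
            raise RuntimeError("distractor disc intersects the reference mask")

    return PhantomSample(
        image=image.astype(np.float32),
        mask=mask,
        metadata={
            "seed": params.seed,
            "image_size": size,
            "n_vertebrae": params.n_vertebrae,
            "n_discs": params.n_discs,
            "target_disc_indices": tuple(params.target_disc_indices),
            "clean_disc_intensity_range": (
                float(clean[mask > 0].min()),
                float(clean[mask > 0].max()),
            ),
        },
    )


def generate_dataset(n: int, params: PhantomParams, out_dir: str | Path) -> Path:
    """Write ``n`` image/mask PNG pairs plus a CSV manifest; return its path.

    Per-sample seeds are derived reproducibly from ``params.seed`` so the
    whole dataset regenerates bit-identically.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    params.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(params.seed).generate_state(n)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path_image", "path_mask", "seed"])
        for i, s in enumerate(seeds):
            sample = generate_sample(replace(params, seed=int(s)))
            img_path = out_dir / f"img_{i:05d}.png"
            mask_path = out_dir / f"mask_{i:05d}.png"
            fileio.write_image(img_path, sample.image)
            fileio.write_mask(mask_path, sample.mask)
            writer.writerow([img_path.name, mask_path.name, int(s)])
    return manifest_path


def load_dataset(manifest_path: str | Path) -> list[PhantomSample]:
    """Read image/mask pairs listed in a manifest back into memory."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    samples = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            samples.append(
                PhantomSample(
                    image=fileio.read_image(base / row["path_image"]),
                    mask=fileio.read_mask(base / row["path_mask"]),
                    metadata={"seed": int(row["seed"])},
                )
            )
    return samples
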