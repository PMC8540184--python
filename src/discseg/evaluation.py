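"""Instance-aware evaluation of multi-disc segmentations.

The protocol scores a prediction against a reference mask with exactly
``L`` disc instances (default 3).  A predicted image is *correct* when

* its connected-component instance count ``P_i`` equals ``L``, and
* every per-disc discrimination value ``C_ik = |R_ik ∩ S_ik| / |S_ik|``
  (fraction of the reference disc covered by its rank-matched predicted
  region) is at least the cutoff (default 0.70).

Aggregates are the correct count ``B``, accuracy ``A = B / T`` and the
mean binary-foreground IoU over *all* ``T`` images, failures included.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .instance_ops import connected_components, count_instances

__all__ = [
    "EvalConfig",
    "EvalRecord",
    "EvalReport",
    "iou",
    "discrimination",
    "image_correct",
    "accuracy",
    "match_instances",
    "evaluate_dataset",
    "conservative_sample_size",
]


@dataclass(frozen=True)
class EvalConfig:
    """Protocol constants: expected instance count and coverage cutoff."""

    L: int = 3
    c_threshold: float = 0.70

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if not 0.0 < self.c_threshold <= 1.0:
            raise ValueError(f"c_threshold must be in (0, 1], got {self.c_threshold}")


@dataclass
class EvalRecord:
    """Per-image outcome: instance count, coverages, correctness, IoU."""

    image_id: str
    P_i: int
    C_i: tuple[float, ...] | None
    b_i: int
    iou_i: float


@dataclass
class EvalReport:
    T: int
    B: int
    A: float
    mean_iou: float
    records: list[EvalRecord] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {"T": self.T, "B": self.B, "A": self.A, "mean_iou": self.mean_iou}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_id", "P_i", "C_i1", "C_i2", "C_i3", "b_i", "iou_i"])
            for rec in self.records:
                cs = ["" for _ in range(3)] if rec.C_i is None else [f"{c:.6f}" for c in rec.C_i]
                writer.writerow([rec.image_id, rec.P_i, *cs, rec.b_i, f"{rec.iou_i:.6f}"])


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    return mask.astype(bool) if mask.dtype != bool else mask


def iou(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard index |X∩Y| / |X∪Y| of two binary masks.

    Both masks empty counts as perfect agreement (1.0); exactly one empty
    gives 0.0.
    """
    x, y = _as_bool(x), _as_bool(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    union = np.count_nonzero(x | y)
    if union == 0:
        return 1.0
    return np.count_nonzero(x & y) / union


def discrimination(r: np.ndarray, s: np.ndarray) -> float:
    """Coverage |R∩S| / |S| of a reference region ``s`` by a prediction ``r``.

    Pixels of ``r`` outside ``s`` do not reduce the value; an empty
    reference region is an error (the ratio is undefined).
    """
    r, s = _as_bool(r), _as_bool(s)
    if r.shape != s.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {s.shape}")
    s_area = np.count_nonzero(s)
    if s_area == 0:
        raise ValueError("reference region is empty; coverage undefined")
    return np.count_nonzero(r & s) / s_area


def image_correct(p_i: int, c_i: Sequence[float] | None, cfg: EvalConfig | None = None) -> int:
    """Binary correctness: 1 iff ``p_i == L`` and every coverage >= cutoff."""
    cfg = cfg or EvalConfig()
    if p_i != cfg.L:
        return 0
    if c_i is None or len(c_i) != cfg.L:
        raise ValueError(f"expected {cfg.L} coverage values when P_i == L, got {c_i!r}")
    return int(all(c >= cfg.c_threshold for c in c_i))


def accuracy(b: Sequence[int]) -> tuple[int, float]:
    """Return ``(B, A)``: number of correct images and their fraction."""
    if len(b) == 0:
        raise ValueError("empty correctness list")
    B = int(sum(b))
    return B, B / len(b)


def match_instances(
    pred: np.ndarray, ref: np.ndarray, cfg: EvalConfig | None = None
) -> list[tuple[np.ndarray, np.ndarray]] | None:
    """Pair predicted to reference instances by top-to-bottom rank.

    Both arguments are labeled masks (0 background, 1..K instances ordered
    by centroid row).  Returns ``L`` pairs of boolean masks ``(R_k, S_k)``
    when the prediction has exactly ``L`` instances, else ``None`` (the
    image is already an error by the count rule).
    """
    cfg = cfg or EvalConfig()
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if int(ref.max(initial=0)) != cfg.L:
        raise ValueError(f"reference mask must have exactly {cfg.L} instances")
    n_pred = int(pred.max(initial=0))
    if n_pred != cfg.L:
        return None
    return [(pred == k, ref == k) for k in range(1, cfg.L + 1)]


def evaluate_dataset(
    preds: Sequence,
    refs: Sequence[np.ndarray],
    cfg: EvalConfig | None = None,
    ids: Sequence[str] | None = None,
) -> EvalReport:
    """Score every prediction and aggregate into an :class:`EvalReport`.

    ``preds`` may mix labeled-mask arrays and objects exposing a ``labels``
    attribute (pipeline results).  Failed predictions contribute ``b_i = 0``
    and whatever binary-foreground IoU they achieve to the mean.
    """
    cfg = cfg or EvalConfig()
    if len(preds) != len(refs):
        raise ValueError(f"got {len(preds)} predictions but {len(refs)} references")
    if len(preds) == 0:
        raise ValueError("empty dataset")
    if ids is None:
        ids = [str(i) for i in range(len(preds))]

    records: list[EvalRecord] = []
    for image_id, pred, ref in zip(ids, preds, refs):
        labels = np.asarray(getattr(pred, "labels", pred))
        ref = np.asarray(ref)
        p_i = count_instances(labels > 0)
        pairs = None
        if p_i == cfg.L:
            # relabel defensively: pairing is defined on top-to-bottom ranks
            ranked = connected_components(labels > 0)
            pairs = match_instances(ranked, ref, cfg)
        if pairs is None:
            c_i, b_i = None, 0
        else:
            c_i = tuple(discrimination(r, s) for r, s in pairs)
            b_i = image_correct(p_i, c_i, cfg)
        records.append(
            EvalRecord(image_id=image_id, P_i=p_i, C_i=c_i, b_i=b_i, iou_i=iou(labels > 0, ref > 0))
        )

    B, A = accuracy([rec.b_i for rec in records])
    mean_iou = float(np.mean([rec.iou_i for rec in records]))
    return EvalReport(T=len(records), B=B, A=A, mean_iou=mean_iou, records=records)


def conservative_sample_size(confidence: float = 0.95, sd: float = 0.01, margin: float = 0.0004) -> int:
    """Most conservative sample size from the normal-approximation interval.

    ``n = ceil((z * sd / margin)^2)`` with ``z`` the two-sided normal
    quantile of the confidence level.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if margin <= 0:
        raise ValueError(f"margin must be positive, got {margin}")
    z = norm.ppf(0.5 + confidence / 2.0)
    return math.ceil((z * sd / margin) ** 2)
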