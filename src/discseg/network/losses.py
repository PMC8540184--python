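"""Focal loss for binary dense prediction.

Per pixel, with ``p_t`` the predicted probability of the true class
(``p`` on foreground, ``1 - p`` on background):

    FL(p_t) = -alpha * (1 - p_t)^gamma * log(p_t)

averaged over all pixels.  ``gamma = 0`` with ``alpha = 1`` reduces to
plain mean binary cross-entropy; ``gamma > 0`` down-weights easy pixels,
which matters with small foreground discs on large backgrounds.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["focal_loss"]

_EPS = 1e-6


def focal_loss(
    prob: Tensor | np.ndarray,
    target: np.ndarray,
    focal_alpha: float = 0.25,
    focal_gamma: float = 2.0,
) -> Tensor:
    """Scalar focal loss of a probability field against a binary target.

    Probabilities are clamped to [eps, 1-eps] so the loss is finite; it is
    zero (in the clamped limit) iff the prediction is confidently correct
    everywhere.
    """
    if not isinstance(prob, Tensor):
        prob = Tensor(prob)
    target = np.asarray(target)
    if target.shape != prob.data.shape:
        raise ValueError(f"shape mismatch: prob {prob.data.shape} vs target {target.shape}")
    if focal_alpha <= 0 or focal_alpha > 1:
        raise ValueError(f"focal_alpha must be in (0, 1], got {focal_alpha}")
    if focal_gamma < 0:
        raise ValueError(f"focal_gamma must be >= 0, got {focal_gamma}")

    fg = target.astype(bool)
    p = np.clip(prob.data, _EPS, 1.0 - _EPS)
    pt = np.where(fg, p, 1.0 - p)
    log_pt = np.log(pt)
    one_minus = 1.0 - pt
    per_pixel = -focal_alpha * one_minus**focal_gamma * log_pt
    n = per_pixel.size
    out_data = np.float32(per_pixel.mean())

    def backward(g):
        if not prob.requires_grad:
            return
        # d/dpt [-(1-pt)^g log pt] = g*(1-pt)^(g-1)*log pt - (1-pt)^g / pt
        # one_minus >= eps by the clamp, so a negative exponent is safe
        dl_dpt = focal_alpha * (
            focal_gamma * one_minus ** (focal_gamma - 1.0) * log_pt
            if focal_gamma > 0
            else np.zeros_like(pt)
        )
        dl_dpt = dl_dpt - focal_alpha * one_minus**focal_gamma / pt
        sign = np.where(fg, 1.0, -1.0)
        prob.accumulate((g * dl_dpt * sign / n).astype(np.float32))

    return Tensor(out_data, _parents=(prob,), _backward=backward)
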