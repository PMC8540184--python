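"""Adam training loop, prediction and binarization for the segmentation nets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Parameter
from .losses import focal_loss
from .multiresunet import MultiResUNet

__all__ = ["TrainConfig", "TrainingDivergedError", "Adam", "train", "predict", "binarize"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    seed: int = 0
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError(f"binarize_threshold must be in (0, 1), got {self.binarize_threshold}")


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite."""


class Adam:
    def __init__(self, params: list[Parameter], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def train(
    model: MultiResUNet,
    inputs: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig,
) -> list[float]:
    """Train in place on (N, C, H, W) inputs / (N, H, W) binary targets.

    Returns the per-epoch mean loss trace; deterministic for a fixed
    config seed and model initialization.
    """
    inputs = np.asarray(inputs, dtype=np.float32)
    targets = np.asarray(targets).astype(bool)
    if inputs.ndim != 4 or targets.ndim != 3 or inputs.shape[0] != targets.shape[0]:
        raise ValueError(f"bad dataset shapes: inputs {inputs.shape}, targets {targets.shape}")
    if inputs.shape[0] == 0:
        raise ValueError("empty training dataset")

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(list(model.parameters()), lr=cfg.learning_rate)
    model.set_training(True)
    n = inputs.shape[0]
    trace: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            prob = model.forward(inputs[idx])
            loss = focal_loss(
                prob, targets[idx][:, None], cfg.focal_alpha, cfg.focal_gamma
            )
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {len(trace) + 1}; lower the learning rate"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))
    model.set_training(False)
    return trace


def predict(model: MultiResUNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probability for one (C, H, W) or (H, W) input."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = image[None]
    if image.ndim != 3:
        raise ValueError(f"expected (C, H, W) or (H, W) input, got shape {image.shape}")
    if image.shape[0] != model.config.input_channels:
        raise ValueError(
            f"model expects {model.config.input_channels} channels, got {image.shape[0]}"
        )
    model.set_training(False)
    return model.forward(image[None]).data[0, 0]


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Boolean mask of pixels with probability >= threshold."""
    return np.asarray(prob) >= threshold
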