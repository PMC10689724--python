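"""Training objectives: soft Dice, binary cross-entropy, their sum, and L2.

All losses are evaluated batch-wise: the soft Dice overlap is computed
over every pixel in the batch jointly (not averaged per sample), which
matters for slices with few or no lesion pixels.  Each loss returns a
scalar autodiff Tensor with an analytic gradient with respect to the
predicted probabilities.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import Tensor

LOSS_KINDS = ("dice", "bce", "dice_bce", "l2")


@dataclasses.dataclass(frozen=True)
class LossSpec:
    """Loss selector with stability constants and combination weights."""

    kind: str = "dice_bce"
    dice_smoothing: float = 1.0
    bce_eps: float = 1e-7
    weights: tuple[float, float] = (1.0, 1.0)  # (dice, bce) for dice_bce

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}")
        w1, w2 = self.weights
        if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
            raise ValueError("weights must be non-negative, not both zero")
        if self.dice_smoothing <= 0:
            raise ValueError("dice_smoothing must be positive")


def _check(pred: Tensor, target: np.ndarray) -> np.ndarray:
    t = np.asarray(target, dtype=np.float32)
    if pred.data.shape != t.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.data.shape} vs target {t.shape}"
        )
    if not np.isin(np.unique(t), (0.0, 1.0)).all():
        raise ValueError("target must be binary")
    return t


def dice_loss(pred: Tensor, target, smoothing: float = 1.0) -> Tensor:
    """1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s), over the whole batch."""
    t = _check(pred, target)
    p = pred.data
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum() + smoothing)
    num = 2.0 * inter + smoothing
    res = Tensor(1.0 - num / denom, parents=(pred,))

    def backward(grad):
        # d/dp [num/denom] = (2t*denom - num) / denom^2
        g = -(2.0 * t * denom - num) / denom**2
        pred._accumulate(grad * g)

    res._backward = backward
    return res


def bce_loss(pred: Tensor, target, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with probability clamping."""
    t = _check(pred, target)
    p = np.clip(pred.data, eps, 1.0 - eps)
    n = p.size
    val = -(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean()
    res = Tensor(val, parents=(pred,))

    def backward(grad):
        inside = (pred.data > eps) & (pred.data < 1.0 - eps)
        g = (p - t) / (p * (1.0 - p) * n)
        pred._accumulate(grad * g * inside)

    res._backward = backward
    return res


def l2_loss(pred: Tensor, target) -> Tensor:
    """Mean squared difference between probabilities and binary target."""
    t = _check(pred, target)
    diff = pred.data - t
    res = Tensor(float((diff**2).mean()), parents=(pred,))

    def backward(grad):
        pred._accumulate(grad * 2.0 * diff / diff.size)

    res._backward = backward
    return res


def compute_loss(pred: Tensor, target, spec: LossSpec = LossSpec()) -> Tensor:
    """Evaluate the configured loss on one batch."""
    if spec.kind == "dice":
        return dice_loss(pred, target, spec.dice_smoothing)
    if spec.kind == "bce":
        return bce_loss(pred, target, spec.bce_eps)
    if spec.kind == "l2":
        return l2_loss(pred, target)
    w1, w2 = spec.weights
    d = dice_loss(pred, target, spec.dice_smoothing)
    b = bce_loss(pred, target, spec.bce_eps)
    res = Tensor(w1 * d.data + w2 * b.data, parents=(d, b))

    def backward(grad):
        d._accumulate(grad * w1)
        b._accumulate(grad * w2)

    res._backward = backward
    return res
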