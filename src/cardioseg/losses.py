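"""Multiclass soft Dice objective.

For class c with predicted probabilities p_ic and one-hot ground truth g_ic,

    Dice_c = (2 * sum_i p_ic g_ic + smooth) / (sum_i p_ic + sum_i g_ic + smooth + eps)

and the training loss is 1 - (1/C) * sum_c Dice_c, averaged over all C
classes including background.  `smooth` defaults to 0 and `eps` to 1e-7;
eps only guards the empty-class denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, LabelError, StructuralError
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass
class LossConfig:
    n_classes: int = 3
    smooth: float = 0.0
    epsilon: float = 1e-7

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.smooth < 0:
            raise ConfigError("smooth must be non-negative")


def one_hot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    """Exact indicator encoding; channel axis first (C,H,W) or (N,C,H,W)."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= n_classes:
        bad = sorted(v for v in np.unique(mask) if v < 0 or v >= n_classes)
        raise LabelError(f"mask value(s) {bad} outside [0, {n_classes})")
    eye = np.eye(n_classes, dtype=np.float32)
    enc = eye[mask.astype(np.int64)]               # (..., H, W, C)
    return np.moveaxis(enc, -1, -3)


def _sum_axes(ndim: int) -> tuple[int, ...]:
    # sum over every axis except the class axis (first for CHW, second for NCHW)
    return (1, 2) if ndim == 3 else (0, 2, 3)


def dice_per_class(p, g, cfg: LossConfig | None = None):
    """Soft per-class Dice coefficients.

    `p` may be a Tensor (training path; float32, differentiable, returns a
    Tensor) or a plain array (evaluation path; computed in float64, returns
    an ndarray).  `g` is a one-hot array.  Shapes (C,H,W) or (N,C,H,W); the
    sums run over pixels (and batch).
    """
    cfg = cfg or LossConfig()
    g = np.asarray(g)
    if tuple(p.shape) != g.shape:
        raise StructuralError(f"probability map {tuple(p.shape)} and one-hot "
                              f"mask {g.shape} disagree")
    axes = _sum_axes(g.ndim)
    if isinstance(p, Tensor):
        gf = g.astype(np.float32)
        inter = T.tsum(T.mul(p, gf), axis=axes)
        denom = T.add(T.tsum(p, axis=axes), gf.sum(axis=axes))
        num = T.add(T.mul(inter, 2.0), cfg.smooth)
        return T.div(num, T.add(denom, cfg.smooth + cfg.epsilon))
    p64 = np.asarray(p, dtype=np.float64)
    g64 = g.astype(np.float64)
    inter = (p64 * g64).sum(axis=axes)
    denom = p64.sum(axis=axes) + g64.sum(axis=axes)
    return (2.0 * inter + cfg.smooth) / (denom + cfg.smooth + cfg.epsilon)


def multiclass_dice_loss(p, g, cfg: LossConfig | None = None):
    """1 minus the unweighted mean of the per-class Dice coefficients.

    Tensor in, Tensor out (differentiable); array in, float out.
    """
    cfg = cfg or LossConfig()
    dice = dice_per_class(p, g, cfg)
    if isinstance(dice, Tensor):
        return T.add(T.mul(T.tmean(dice), -1.0), 1.0)
    return float(1.0 - dice.mean())
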