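"""Segmentation losses: soft Dice, log-cosh Dice, focal, and focal Dice.

The compound focal Dice loss is

    L = w1 * FocalLoss + w2 * (DiceLoss)^gamma * log(cosh(DiceLoss))

where DiceLoss = 1 - soft Dice (averaged over foreground classes) and the
(DiceLoss)^gamma factor adaptively up-weights the log-cosh Dice term on
poorly segmented batches and damps it as segmentation improves.  The
default weighting is w1:w2 = 4:1.

All loss functions accept either a plain numpy probability array or an
autograd :class:`~scunet.nn.Tensor`; given a Tensor they return a scalar
Tensor through which gradients flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.tensor import Tensor, as_tensor

__all__ = ["LossWeights", "LossValue", "soft_dice_loss", "log_cosh_dice_loss",
           "focal_loss", "focal_dice_loss"]

_EPS = 1e-6          # Dice smoothing; keeps empty-class ratios at 1
_P_FLOOR = 1e-7      # probability clamp before log


@dataclass(frozen=True)
class LossWeights:
    """Weights of the compound loss.

    omega1/omega2 balance focal vs log-cosh Dice (default 4:1); ``gamma``
    is the adaptive exponent on DiceLoss; ``focal_gamma`` and
    ``focal_alpha`` parameterise the focal term.
    """

    omega1: float = 4.0
    omega2: float = 1.0
    gamma: float = 1.0
    focal_gamma: float = 2.0
    focal_alpha: tuple[float, ...] | None = None   # per-class; None = uniform 1

    def __post_init__(self):
        if self.omega1 < 0 or self.omega2 < 0 or self.omega1 + self.omega2 <= 0:
            raise ValueError("omega1, omega2 must be >= 0 and not both zero")
        if self.gamma < 0 or self.focal_gamma < 0:
            raise ValueError("exponents must be >= 0")


@dataclass(frozen=True)
class LossValue:
    """Total compound loss plus its components (floats); ``total_tensor``
    carries the autograd graph when the input was a Tensor."""

    total: float
    focal: float
    dice: float
    log_cosh_dice: float
    focal_dice_term: float
    total_tensor: Tensor | None = field(default=None, compare=False, repr=False)


def _prep(prob, target):
    prob = as_tensor(prob)
    if prob.ndim == 3:
        prob = prob.reshape(1, *prob.shape)
    target = np.asarray(target)
    if target.ndim == 2:
        target = target[None]
    n, c, h, w = prob.data.shape
    if target.shape != (n, h, w):
        raise ValueError(f"target shape {target.shape} does not match "
                         f"probabilities {prob.data.shape}")
    if target.min() < 0 or target.max() >= c:
        raise ValueError(f"target labels must lie in [0, {c - 1}]")
    onehot = np.zeros((n, c, h, w), dtype=prob.data.dtype)
    np.put_along_axis(onehot, target[:, None], 1.0, axis=1)
    return prob, target, onehot


def soft_dice_loss(prob, target, *, eps: float = _EPS):
    """1 - soft Dice, averaged over the foreground classes.

    Per class c >= 1: dice_c = (2 sum p_c y_c + eps) / (sum p_c + sum y_c + eps);
    classes absent from both prediction mass and truth contribute dice 1
    through the eps smoothing, so an all-background exact match costs 0.
    """
    prob, _, onehot = _prep(prob, target)
    c = prob.data.shape[1]
    inter = (prob * onehot).sum(axis=(0, 2, 3))      # (C,)
    sums = prob.sum(axis=(0, 2, 3)) + Tensor(onehot.sum(axis=(0, 2, 3)))
    dice = (inter * 2.0 + eps) / (sums + eps)
    fg = np.zeros(c)
    fg[1:] = 1.0                                     # foreground classes only
    mean_dice = (dice * Tensor(fg)).sum() * (1.0 / (c - 1))
    return 1.0 - mean_dice


def log_cosh_dice_loss(dice_loss):
    """log(cosh(DiceLoss)); smooth, convex surrogate of the Dice loss."""
    if isinstance(dice_loss, (int, float)) and dice_loss < 0:
        raise ValueError("dice_loss must be >= 0")
    if isinstance(dice_loss, Tensor):
        return dice_loss.logcosh()
    return float(np.log(np.cosh(dice_loss)))


def focal_loss(prob, target, weights: LossWeights = LossWeights()):
    """Mean of -alpha_c (1 - p_t)^focal_gamma log(p_t) over pixels."""
    prob, target_arr, onehot = _prep(prob, target)
    c = prob.data.shape[1]
    if weights.focal_alpha is None:
        alpha_map = 1.0
    else:
        alpha = np.asarray(weights.focal_alpha, dtype=float)
        if alpha.shape != (c,):
            raise ValueError(f"focal_alpha must have {c} entries")
        alpha_map = Tensor(alpha[target_arr])
    p_t = (prob * onehot).sum(axis=1).clip(_P_FLOOR, 1.0)
    modulator = (1.0 - p_t) ** weights.focal_gamma
    return (alpha_map * modulator * (-(p_t.log()))).mean()


def focal_dice_loss(prob, target,
                    weights: LossWeights = LossWeights()) -> LossValue:
    """Compound loss: w1*Focal + w2*(DiceLoss)^gamma*log(cosh(DiceLoss)).

    DiceLoss is computed over the whole batch (one Dice per class across
    all images) before the adaptive exponent is applied.
    """
    keep_graph = isinstance(prob, Tensor) and prob.requires_grad
    fl = focal_loss(prob, target, weights)
    dl = soft_dice_loss(prob, target)
    lc = log_cosh_dice_loss(dl)
    fd_term = (dl ** weights.gamma) * lc
    total = weights.omega1 * fl + weights.omega2 * fd_term
    return LossValue(
        total=float(total.data),
        focal=float(fl.data),
        dice=float(dl.data),
        log_cosh_dice=float(lc.data),
        focal_dice_term=float(fd_term.data),
        total_tensor=total if keep_graph else None,
    )
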