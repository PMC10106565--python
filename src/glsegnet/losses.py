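"""Hybrid segmentation loss: Dice + BCE + SSIM + edge preservation.

The total loss is the convex combination

    L = alpha*L1 + beta*L2 + gamma*L3 + theta*L4,   alpha+beta+gamma+theta = 1

with L1 = 1 - Dice coefficient (region overlap), L2 = binary cross-entropy
(per-pixel classification), L3 = 1 - mean windowed SSIM (structure), and
L4 = mean norm of the difference of 5-point Laplacians (edges).  All terms are
differentiable with respect to the prediction and vanish when the prediction
equals a binary ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .config import LossWeights
from .exceptions import ConfigurationError

__all__ = ["LossWeights", "LossReport", "dice_term", "bce_term", "ssim_term",
           "edge_term", "hybrid", "gaussian_window"]


@dataclass
class LossReport:
    """Scalar values of the four terms and their weighted total."""

    l1: float
    l2: float
    l3: float
    l4: float
    total: float


def _tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def dice_term(pred, gt, eps: float = 1e-6) -> Tensor:
    """1 - Dice similarity coefficient, smoothed so that two empty masks
    score a perfect 0."""
    pred, gt = _tensor(pred), _tensor(gt)
    inter = (pred * gt).sum()
    dsc = (2.0 * inter + eps) / (pred.sum() + gt.sum() + eps)
    return 1.0 - dsc


def bce_term(pred, gt, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with the prediction clamped to [eps, 1-eps]."""
    pred, gt = _tensor(pred), _tensor(gt)
    p = pred.clip(eps, 1.0 - eps)
    ll = gt * p.log() + (1.0 - gt) * (1.0 - p).log()
    return -ll.mean()


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Normalized separable Gaussian window used by the SSIM term."""
    r = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(r * r) / (2.0 * sigma * sigma))
    k = np.outer(g, g)
    return k / k.sum()


def ssim_term(pred, gt, window: int = 11, sigma: float = 1.5,
              c1: float = 0.01 ** 2, c2: float = 0.03 ** 2) -> Tensor:
    """1 - mean windowed SSIM between single-channel images in [0, 1].

    Local means, variances and the covariance are computed under a Gaussian
    window over all fully-contained (valid) window positions.
    """
    pred, gt = _tensor(pred), _tensor(gt)
    p = _as_nchw(pred)
    g = _as_nchw(gt)
    h, w = p.shape[2], p.shape[3]
    if window > h or window > w:
        raise ConfigurationError(
            f"SSIM window {window} larger than image {h}x{w}")
    # the Gaussian window is separable: blur with two 1-D passes
    r = np.arange(window, dtype=np.float64) - (window - 1) / 2.0
    g1 = np.exp(-(r * r) / (2.0 * sigma * sigma))
    g1 /= g1.sum()
    kv = Tensor(g1.reshape(1, 1, window, 1))
    kh = Tensor(g1.reshape(1, 1, 1, window))

    def blur(t):
        return ag.conv2d(ag.conv2d(t, kv), kh)

    mu_p = blur(p)
    mu_g = blur(g)
    var_p = blur(p * p) - mu_p * mu_p
    var_g = blur(g * g) - mu_g * mu_g
    cov = blur(p * g) - mu_p * mu_g
    num = (2.0 * mu_p * mu_g + c1) * (2.0 * cov + c2)
    den = (mu_p * mu_p + mu_g * mu_g + c1) * (var_p + var_g + c2)
    return 1.0 - (num / den).mean()


_LAPLACIAN = np.array([[0.0, 1.0, 0.0],
                       [1.0, -4.0, 1.0],
                       [0.0, 1.0, 0.0]])


def laplacian(img) -> Tensor:
    """5-point Laplacian (second differences in x and y) with replicate
    borders, same spatial size as the input."""
    x = _as_nchw(_tensor(img))
    padded = ag.pad2d(x, 1, mode="replicate")
    return ag.conv2d(padded, Tensor(_LAPLACIAN.reshape(1, 1, 3, 3)))


def edge_term(pred, gt, norm: str = "l1") -> Tensor:
    """Normalized difference of the Laplacians of prediction and truth."""
    diff = laplacian(pred) - laplacian(gt)
    if norm == "l1":
        return diff.abs().mean()
    if norm == "l2":
        n = diff.data[0, 0].size
        return ((diff * diff).sum()) ** 0.5 * (1.0 / n)
    raise ConfigurationError(f"edge norm must be 'l1' or 'l2', got {norm!r}")


def hybrid(pred, gt, weights: LossWeights | None = None, *,
           ssim_window: int = 11, edge_norm: str = "l1") -> tuple[Tensor, LossReport]:
    """Weighted combination of the four terms.

    Returns the differentiable total (for ``backward``) together with a
    :class:`LossReport` of plain floats.
    """
    if weights is None:
        weights = LossWeights()
    pred, gt = _tensor(pred), _tensor(gt)
    l1 = dice_term(pred, gt)
    l2 = bce_term(pred, gt)
    l3 = ssim_term(pred, gt, window=ssim_window)
    l4 = edge_term(pred, gt, norm=edge_norm)
    total = (weights.alpha * l1 + weights.beta * l2
             + weights.gamma * l3 + weights.theta * l4)
    report = LossReport(l1.item(), l2.item(), l3.item(), l4.item(), total.item())
    return total, report


def _as_nchw(t: Tensor) -> Tensor:
    if t.ndim == 2:
        return t.reshape(1, 1, *t.shape)
    if t.ndim == 3:
        return t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    if t.ndim == 4:
        return t
    raise ConfigurationError(f"expected 2-4 dims, got shape {t.shape}")
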