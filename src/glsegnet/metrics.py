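"""Evaluation indices: MeanDice, MeanIoU, weighted F-measure,
Structure-measure and Enhanced-alignment measure.

Dice/IoU are plain set-overlap ratios of binarized masks.  The other three
follow their published definitions:

* **weighted F-measure** (Margolin et al. 2014): the per-pixel error is
  propagated to foreground errors through a Gaussian neighborhood and
  down-weighted with distance from the object, yielding weighted
  precision/recall combined with beta = 1.
* **Structure-measure** (Fan et al. 2017): 0.5 * object-aware + 0.5 *
  region-aware structural similarity between the continuous prediction and
  the binary mask.
* **Enhanced-alignment measure** (Fan et al. 2018): mean of the enhanced
  alignment matrix built from mean-centered bias matrices of the binarized
  prediction and the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .exceptions import ShapeError

__all__ = ["dice_iou", "weighted_fmeasure", "structure_measure",
           "enhanced_measure", "evaluate_set", "MetricsReport", "binarize"]

_EPS = np.finfo(np.float64).eps


def binarize(pred: np.ndarray, threshold: float | str = 0.5) -> np.ndarray:
    """Threshold a probability map; ``threshold='adaptive'`` uses 2x its mean."""
    pred = np.asarray(pred, dtype=np.float64)
    if threshold == "adaptive":
        t = min(2.0 * pred.mean(), 1.0 - _EPS)
    else:
        t = float(threshold)
    return (pred >= t).astype(np.uint8)


def _check_binary(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return m.astype(bool)


def dice_iou(pred_bin: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    """Dice = 2|P&G|/(|P|+|G|), IoU = |P&G|/|P|G|; both-empty -> (1, 1)."""
    p = _check_binary(pred_bin, "prediction")
    g = _check_binary(gt, "ground truth")
    if p.shape != g.shape:
        raise ShapeError(f"shape mismatch {p.shape} vs {g.shape}")
    inter = np.logical_and(p, g).sum()
    union = np.logical_or(p, g).sum()
    total = p.sum() + g.sum()
    if total == 0:
        return 1.0, 1.0
    return 2.0 * inter / total, inter / union


def weighted_fmeasure(pred: np.ndarray, gt: np.ndarray, beta: float = 1.0) -> float:
    """Weighted F-beta of a continuous prediction against a binary mask."""
    fg = np.asarray(pred, dtype=np.float64)
    g = _check_binary(gt, "ground truth")
    if fg.shape != g.shape:
        raise ShapeError(f"shape mismatch {fg.shape} vs {g.shape}")
    if not g.any():
        return 1.0 if fg.max() == 0 else 0.0

    e = np.abs(fg - g)
    dst = ndimage.distance_transform_edt(~g)
    et = e.copy()
    nh, nw = _nearest_foreground(g)
    et[~g] = e[nh, nw]                  # error at the nearest foreground pixel
    k = _gauss_kernel(7, 5.0)
    ea = ndimage.convolve(et, k, mode="constant", cval=0.0)
    min_e_ea = e.copy()
    sel = g & (ea < e)
    min_e_ea[sel] = ea[sel]
    b = np.ones_like(fg)
    b[~g] = 2.0 - np.exp(np.log(0.5) / 5.0 * dst[~g])
    ew = min_e_ea * b
    tpw = g.sum() - ew[g].sum()
    fpw = ew[~g].sum()
    r = 1.0 - ew[g].mean()
    p = tpw / (tpw + fpw + _EPS)
    q = (1 + beta ** 2) * r * p / (r + (beta ** 2) * p + _EPS)
    return float(np.clip(q, 0.0, 1.0))


def _nearest_foreground(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of the nearest foreground pixel for every background pixel.

    Squared grid distances are integers, so exact ties are possible; they are
    broken deterministically toward the lexicographically smallest (row, col).
    """
    fgc = np.argwhere(g)                      # row-major, i.e. lexicographic
    bgc = np.argwhere(~g)
    tree = cKDTree(fgc)
    k = min(2, len(fgc))
    dd, ii = tree.query(bgc, k=k)
    if k == 1:
        nearest = fgc[np.atleast_1d(ii)]
    else:
        nearest = fgc[ii[:, 0]].copy()
        tied = np.nonzero(dd[:, 1] - dd[:, 0] < 1e-9)[0]
        for t in tied:
            cands = tree.query_ball_point(bgc[t], dd[t, 0] + 1e-6)
            pts = fgc[cands]
            d2 = ((pts - bgc[t]) ** 2).sum(axis=1)
            best = pts[d2 == d2.min()]
            order = np.lexsort((best[:, 1], best[:, 0]))
            nearest[t] = best[order[0]]
    return nearest[:, 0], nearest[:, 1]


def _gauss_kernel(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(r * r) / (2.0 * sigma * sigma))
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_region(p: np.ndarray, g: np.ndarray) -> float:
    # structural-similarity score of one region block (region term helper)
    n = p.size
    if n <= 1:
        return 1.0 if p.size and float(p.flat[0]) == float(g.flat[0]) else 0.0
    x, y = p.mean(), g.mean()
    sx = ((p - x) ** 2).sum() / (n - 1)
    sy = ((g - y) ** 2).sum() / (n - 1)
    sxy = ((p - x) * (g - y)).sum() / (n - 1)
    a = 4.0 * x * y * sxy
    b = (x * x + y * y) * (sx + sy)
    if a != 0:
        return float(a / (b + _EPS))
    return 1.0 if b == 0 else 0.0


def _object_score(x: np.ndarray, region: np.ndarray) -> float:
    if not region.any():
        return 0.0
    vals = x[region]
    mean, std = vals.mean(), vals.std()
    return float(2.0 * mean / (mean * mean + 1.0 + 2.0 * std + _EPS))


def structure_measure(pred: np.ndarray, gt: np.ndarray) -> float:
    """Structure-measure of a continuous prediction against a binary mask."""
    fg = np.asarray(pred, dtype=np.float64)
    g = _check_binary(gt, "ground truth")
    if fg.shape != g.shape:
        raise ShapeError(f"shape mismatch {fg.shape} vs {g.shape}")
    mu = g.mean()
    if mu == 0.0:          # no object: reward empty predictions
        return float(1.0 - fg.mean())
    if mu == 1.0:          # everything is object
        return float(fg.mean())

    # object-aware term: foreground/background scores mixed by object area
    s_obj = mu * _object_score(fg, g) + (1.0 - mu) * _object_score(1.0 - fg, ~g)

    # region-aware term: split at the object centroid, SSIM-like per block
    rows, cols = np.nonzero(g)
    cy = int(round(rows.mean()))
    cx = int(round(cols.mean()))
    h, w = g.shape
    area = h * w
    weights, scores = [], []
    for rs, cs in ((slice(0, cy + 1), slice(0, cx + 1)),
                   (slice(0, cy + 1), slice(cx + 1, w)),
                   (slice(cy + 1, h), slice(0, cx + 1)),
                   (slice(cy + 1, h), slice(cx + 1, w))):
        gb = g[rs, cs]
        weights.append(gb.size / area)
        scores.append(_ssim_region(fg[rs, cs], gb.astype(np.float64)))
    s_reg = sum(wt * sc for wt, sc in zip(weights, scores))
    return float(np.clip(0.5 * s_obj + 0.5 * s_reg, 0.0, 1.0))


def enhanced_measure(pred_bin: np.ndarray, gt: np.ndarray) -> float:
    """Enhanced-alignment measure between two binary masks."""
    p = _check_binary(pred_bin, "prediction").astype(np.float64)
    g = _check_binary(gt, "ground truth").astype(np.float64)
    if p.shape != g.shape:
        raise ShapeError(f"shape mismatch {p.shape} vs {g.shape}")
    if g.sum() == 0:
        enhanced = 1.0 - p
    elif g.sum() == g.size:
        enhanced = p
    else:
        phi_g = g - g.mean()
        phi_p = p - p.mean()
        align = 2.0 * phi_g * phi_p / (phi_g ** 2 + phi_p ** 2 + _EPS)
        enhanced = (align + 1.0) ** 2 / 4.0
    em = enhanced.sum() / (g.size - 1 + _EPS)
    return float(np.clip(em, 0.0, 1.0))


@dataclass
class MetricsReport:
    """Per-image metric rows and their arithmetic means."""

    per_image: list[dict] = field(default_factory=list)

    @property
    def means(self) -> dict[str, float]:
        keys = ("dice", "iou", "wfm", "sm", "em")
        n = len(self.per_image)
        if n == 0:
            return {k: float("nan") for k in keys}
        return {k: float(np.mean([row[k] for row in self.per_image])) for k in keys}


def evaluate_set(preds, gts, threshold: float | str = 0.5) -> MetricsReport:
    """Score aligned lists of probability maps and binary masks.

    Dice/IoU/Em consume the prediction binarized at ``threshold``; the
    weighted F-measure and Structure-measure consume the continuous map.
    """
    preds, gts = list(preds), list(gts)
    if len(preds) != len(gts):
        raise ValueError(f"{len(preds)} predictions vs {len(gts)} ground truths")
    report = MetricsReport()
    for pred, gt in zip(preds, gts):
        pred = np.asarray(pred, dtype=np.float64).squeeze()
        gt = np.asarray(gt).squeeze()
        pb = binarize(pred, threshold)
        dice, iou = dice_iou(pb, gt)
        report.per_image.append({
            "dice": dice,
            "iou": iou,
            "wfm": weighted_fmeasure(pred, gt),
            "sm": structure_measure(pred, gt),
            "em": enhanced_measure(pb, gt),
        })
    return report
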