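"""Segmentation losses.

The primary loss is a *dual cross entropy*: the standard per-voxel
multiclass cross entropy plus a weighted second cross-entropy term that
penalizes confident foreground probability on background voxels,

    L = CE + fp_weight * L_fp,
    CE   = -mean_v log p(t_v | v),
    L_fp = -(1/V) * sum_{v: t_v = 0} sum_{c >= 1} log(1 - p(c | v) + eps).

With ``fp_weight = 0`` the loss reduces exactly to standard cross entropy.
Probabilities are clamped to ``[eps, 1 - eps]`` inside the logarithms, so
the loss is finite for any prediction.  A Dice loss and an independent
per-channel sigmoid BCE (for multilabel heads) are provided as
alternatives.
"""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Var


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-axis softmax of a (C, ...) array."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def dual_cross_entropy(scores: Var, target: np.ndarray, fp_weight: float = 1.0,
                       eps: float = 1e-7) -> Var:
    """Dual cross-entropy loss on per-voxel class scores.

    Parameters
    ----------
    scores : Var, shape (n_classes, X, Y, Z)
        Unnormalized class scores (logits).
    target : int ndarray, shape (X, Y, Z)
        Per-voxel class labels; 0 is background.
    fp_weight : float
        Weight of the false-positive term; 0 gives plain cross entropy.
    """
    n_classes = scores.data.shape[0]
    target = np.asarray(target)
    if target.shape != scores.data.shape[1:]:
        raise ValueError(f"target shape {target.shape} != score grid {scores.data.shape[1:]}")
    if target.min() < 0 or target.max() >= n_classes:
        raise ValueError(f"target labels must be in [0, {n_classes - 1}]")

    z = scores.data.reshape(n_classes, -1).astype(np.float64)
    t = target.reshape(-1)
    v_total = t.size
    p = softmax(z)
    p_clamped = np.clip(p, eps, 1.0 - eps)

    onehot = np.zeros_like(z)
    onehot[t, np.arange(v_total)] = 1.0
    ce = -np.log(p_clamped[t, np.arange(v_total)]).mean()
    # gradient of mean -log softmax wrt logits
    grad = (p - onehot) / v_total

    fp_term = 0.0
    if fp_weight != 0.0 and n_classes > 1:
        bg = t == 0
        if bg.any():
            q = 1.0 - p[1:, bg]  # probability of "not class c" on background voxels
            q = np.clip(q, eps, None)
            fp_term = -np.log(q).sum() / v_total
            # d/dz of -sum log(1 - p_c): for c>=1, g_c = 1/(1-p_c+..)
            gcoef = np.zeros((n_classes, bg.sum()))
            gcoef[1:] = 1.0 / q
            pb = p[:, bg]
            inner = (gcoef * pb).sum(axis=0, keepdims=True)
            grad_fp = (pb * (gcoef - inner)) / v_total
            grad[:, bg] += fp_weight * grad_fp

    loss_val = ce + fp_weight * fp_term
    out = Var(np.asarray(loss_val, dtype=DTYPE), parents=(scores,))
    grad32 = grad.reshape(scores.data.shape).astype(DTYPE)
    out._backward = lambda g: scores._accumulate(g.reshape(()) * grad32)
    return out


def sigmoid_bce(scores: Var, target: np.ndarray, eps: float = 1e-7) -> Var:
    """Independent per-channel binary cross entropy (multilabel head)."""
    target = np.asarray(target, dtype=np.float64)
    if target.shape != scores.data.shape:
        raise ValueError("target shape must match scores shape")
    z = scores.data.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-z))
    p_c = np.clip(p, eps, 1.0 - eps)
    n = z.size
    loss = -(target * np.log(p_c) + (1.0 - target) * np.log(1.0 - p_c)).mean()
    grad = ((p - target) / n).astype(DTYPE)
    out = Var(np.asarray(loss, dtype=DTYPE), parents=(scores,))
    out._backward = lambda g: scores._accumulate(g.reshape(()) * grad)
    return out


def dice_loss(scores: Var, target: np.ndarray, smooth: float = 1.0) -> Var:
    """Soft-Dice loss on the foreground softmax probability (2-class head)."""
    if scores.data.shape[0] != 2:
        raise ValueError("dice_loss expects a 2-class score map")
    target = np.asarray(target, dtype=np.float64).reshape(-1)
    z = scores.data.reshape(2, -1).astype(np.float64)
    p = softmax(z)[1]
    inter = (p * target).sum()
    denom = p.sum() + target.sum()
    loss = 1.0 - (2.0 * inter + smooth) / (denom + smooth)
    # d loss / d p, then through softmax
    dldp = -(2.0 * target * (denom + smooth) - (2.0 * inter + smooth)) / (denom + smooth) ** 2
    grad_p = np.zeros_like(z)
    grad_p[1] = dldp
    inner = (grad_p * softmax(z)).sum(axis=0, keepdims=True)
    grad = softmax(z) * (grad_p - inner)
    out = Var(np.asarray(loss, dtype=DTYPE), parents=(scores,))
    grad32 = grad.reshape(scores.data.shape).astype(DTYPE)
    out._backward = lambda g: scores._accumulate(g.reshape(()) * grad32)
    return out


LOSSES = {"dual_cross_entropy": dual_cross_entropy, "cross_entropy":
          lambda s, t, **kw: dual_cross_entropy(s, t, fp_weight=0.0),
          "dice": lambda s, t, **kw: dice_loss(s, t)}
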