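"""Training objectives.

* ``bce_loss`` — pixel-wise binary cross entropy for the attention branch.
* ``mse_loss`` — mean squared error between predicted and target density.
* ``pn_loss`` — the positive–negative counting loss: the density target's
  support splits the map into an object (positive) region and a
  background (negative) region; the loss is ``|(C_gt - C_O) - C_B|``
  where ``C_O``/``C_B`` are the probability-weighted predicted masses of
  the two regions.  Note this form can cancel opposing errors (excess
  mass inside the positive region offset by background mass); that is a
  property of the definition and is kept as-is.
* ``total_loss`` — ``mse + lambda * bce + gamma * si``.
* ``size_loss`` — L1 between the regressed size limit and the KNN
  pseudo-size target.

All losses are pure functions of numpy arrays.  The ``*_grad`` variants
additionally return the analytic gradient with respect to the
prediction; the training loop consumes those.
"""

from __future__ import annotations

import numpy as np

PROB_EPS = 1e-7  # clamp for probabilities ahead of logarithms


class ShapeMismatchError(ValueError):
    pass


def _as2d(a) -> np.ndarray:
    return np.asarray(getattr(a, "values", a), dtype=np.float64)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")


def bce_loss(pam_pred, pam_gt, reduction: str = "mean") -> float:
    """Binary cross entropy between predicted and target attention maps.

    ``reduction='mean'`` averages over all pixels (scale-free default);
    ``'sum'`` is the strict per-batch summation variant.
    """
    m = _as2d(pam_pred)
    g = _as2d(pam_gt)
    _check_shapes(m, g)
    m = np.clip(m, PROB_EPS, 1.0 - PROB_EPS)
    terms = -(g * np.log(m) + (1.0 - g) * np.log(1.0 - m))
    return float(terms.mean() if reduction == "mean" else terms.sum())


def mse_loss(pred, target) -> float:
    """Mean of squared per-pixel differences."""
    p = _as2d(pred)
    t = _as2d(target)
    _check_shapes(p, t)
    return float(np.mean((p - t) ** 2))


def pn_loss(pred, density_gt, true_count: float, p_pos: float = 1.0) -> float:
    """Positive–negative counting loss over one density map.

    The positive region is the exact support of the target (``gt > 0``).
    With object probability ``p_pos`` there and background probability 1
    off it, the expected positive-region count is ``C_O = sum(P_O*pred)``
    and the background count ``C_B = sum(P_B*pred)``; the loss is
    ``|(true_count - C_O) - C_B|``.
    """
    pr = _as2d(pred)
    gt = _as2d(density_gt)
    _check_shapes(pr, gt)
    if not 0 < p_pos <= 1:
        raise ValueError("p_pos must be in (0,1]")
    pos = gt > 0
    c_o = float(pr[pos].sum() * p_pos)
    c_b = float(pr[pos].sum() * (1.0 - p_pos) + pr[~pos].sum())
    return abs((true_count - c_o) - c_b)


def total_loss(mse: float, bce: float, si: float, lambda_bce: float = 0.1,
               gamma_si: float = 0.1) -> float:
    """Weighted total objective ``mse + lambda*bce + gamma*si``."""
    return float(mse + lambda_bce * bce + gamma_si * si)


def size_loss(d_p: float, d_mean_gt: float) -> float:
    """L1 loss for the size-limit regression."""
    return abs(float(d_p) - float(d_mean_gt))


# ---------------------------------------------------------------------------
# gradient variants used by the training loop
# ---------------------------------------------------------------------------

def bce_grad_wrt_logits(pam_pred: np.ndarray, pam_gt: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(logit) = (sigmoid(logit) - target) / n_pixels."""
    m = np.asarray(pam_pred, np.float64)
    g = np.asarray(pam_gt, np.float64)
    _check_shapes(m, g)
    return (m - g) / m.size


def mse_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    p = np.asarray(pred, np.float64)
    t = np.asarray(target, np.float64)
    _check_shapes(p, t)
    return 2.0 * (p - t) / p.size


def pn_grad(pred: np.ndarray, density_gt: np.ndarray, true_count: float,
            p_pos: float = 1.0) -> np.ndarray:
    pr = np.asarray(pred, np.float64)
    gt = np.asarray(density_gt, np.float64)
    _check_shapes(pr, gt)
    pos = gt > 0
    p_o = np.where(pos, p_pos, 0.0)
    p_b = np.where(pos, 1.0 - p_pos, 1.0)
    inner = (true_count - float((p_o * pr).sum())) - float((p_b * pr).sum())
    return -np.sign(inner) * (p_o + p_b)
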