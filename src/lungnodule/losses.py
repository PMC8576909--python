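"""Training losses and their analytic gradients.

Dice loss comes in the standard sum-denominator form

    DiceLoss(P, T) = 1 - (2|T.P| + s) / (|T| + |P| + s)

(the training default, with a small smoothing constant ``s``) and a
squared-denominator variant 2|T.P| / (|T|^2 + |P|^2).  The classic
closed-form gradient of the squared-denominator coefficient is kept as a
documented reference (``dice_grad_reference``).  Binary cross entropy is
summed over voxels; its gradient with respect to the pre-sigmoid logit
is simply P - T.  The classifier head uses mean negative log likelihood
over one-hot labels.
"""

from __future__ import annotations

import numpy as np

SMOOTH = 1e-5
_EPS = 1e-7


def _as_arrays(P, T):
    P = np.asarray(getattr(P, "values", P), dtype=np.float64)
    T = np.asarray(getattr(T, "values", T), dtype=np.float64)
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs T {T.shape}")
    return P, T


def dice_loss(P, T, smooth: float = SMOOTH, squared: bool = False) -> float:
    """Soft Dice loss; ``squared=True`` uses the |T|^2+|P|^2 denominator."""
    P, T = _as_arrays(P, T)
    inter = (P * T).sum()
    denom = ((P * P).sum() + (T * T).sum()) if squared else (P.sum() + T.sum())
    if denom == 0 and smooth == 0:
        raise ValueError("Dice loss undefined: both masks empty and smoothing disabled")
    return float(1.0 - (2.0 * inter + smooth) / (denom + smooth))


def dice_loss_grad(P, T, smooth: float = SMOOTH) -> np.ndarray:
    """d DiceLoss / dP for the sum-denominator form (used in training)."""
    P, T = _as_arrays(P, T)
    num = 2.0 * (P * T).sum() + smooth
    den = P.sum() + T.sum() + smooth
    return (num - 2.0 * T * den) / (den * den)


def dice_grad_reference(P, T) -> np.ndarray:
    """Closed-form per-voxel gradient 2T(T^2 - P^2) / (T^2 + P^2).

    This is the textbook expression for the voxelwise squared-denominator
    Dice coefficient 2PT/(P^2+T^2), written without the square on the
    denominator; dividing it by (T^2 + P^2) recovers the exact derivative.
    Where T = P = 0 the value is defined as 0 (limit convention).
    """
    P, T = _as_arrays(P, T)
    den = T * T + P * P
    out = np.zeros_like(P)
    nz = den > 0
    out[nz] = 2.0 * T[nz] * (T[nz] ** 2 - P[nz] ** 2) / den[nz]
    return out


def bce_loss(P, T, eps: float = _EPS) -> float:
    """Summed binary cross entropy -sum T ln P + (1-T) ln(1-P)."""
    P, T = _as_arrays(P, T)
    Pc = np.clip(P, eps, 1.0 - eps)
    return float(-(T * np.log(Pc) + (1.0 - T) * np.log(1.0 - Pc)).sum())


def bce_grad_logits(P, T) -> np.ndarray:
    """Gradient of summed BCE w.r.t. the pre-sigmoid logit: P - T."""
    P, T = _as_arrays(P, T)
    return P - T


def nll_loss(P, T_onehot, eps: float = 1e-12) -> float:
    """Mean negative log likelihood -ln(P . T) over a batch.

    ``P`` is (N, K) class probabilities, ``T_onehot`` the matching one-hot
    labels.  Zero probability at the true class is clipped (with a
    warning) rather than returning inf.
    """
    P = np.asarray(P, dtype=np.float64)
    T = np.asarray(T_onehot, dtype=np.float64)
    if P.ndim == 1:
        P, T = P[None], T[None]
    if P.shape != T.shape or P.shape[0] < 1:
        raise ValueError(f"shape mismatch or empty batch: {P.shape} vs {T.shape}")
    p_true = (P * T).sum(axis=1)
    if np.any(p_true <= 0):
        import warnings

        warnings.warn("zero probability at true class; clipping", stacklevel=2)
    return float(-np.log(np.clip(p_true, eps, None)).mean())
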