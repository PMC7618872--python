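"""Training objective: soft Dice overlap plus field-gradient smoothness.

The total loss is ``L = L_Dice(Y, S) + alpha * L_Grad(Phi_ft) +
beta * L_Grad(Phi_bulk)``.  The gradient penalty is evaluated on the
final, twice-input-resolution fields and acts on the displacement
``u = Phi - x`` (so the identity transform costs nothing), summing the
squared Euclidean norm of forward differences in the row and column
directions and normalising by the number of grid points, which makes
``alpha`` and ``beta`` resolution independent.

All functions accept plain numpy arrays or the autodiff ``Tensor``s
used during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DeformationField, DisplacementField

__all__ = ["LossWeights", "dice_loss", "grad_loss", "total_loss"]

_EPS = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """Weights of the fine-tuning (alpha) and bulk (beta) gradient terms."""

    alpha: float = 10_000.0
    beta: float = 10_000.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")


def dice_loss(Y, S, eps: float = _EPS):
    """Soft Dice loss, averaged over channels.

    ``1 - (2 * sum(Y*S) + eps) / (sum(Y) + sum(S) + eps)`` per channel;
    ``Y`` is the binary reference, ``S`` the soft prediction in [0, 1].
    Accepts ``[c, H, W]`` or batched ``[N, c, H, W]`` inputs.
    """
    if Y.shape != S.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {S.shape}")
    inter = (Y * S).sum(axis=(-2, -1))
    denom = Y.sum(axis=(-2, -1)) + S.sum(axis=(-2, -1))
    dice = (inter * 2.0 + eps) / (denom + eps)
    return (dice * (-1.0) + 1.0).mean()


def _displacement(phi):
    if isinstance(phi, DeformationField):
        return phi.displacement.values
    if isinstance(phi, DisplacementField):
        return phi.values
    return phi  # raw array or Tensor of displacements


def grad_loss(phi, normalize_coords: bool = True):
    """Mean squared forward-difference norm of the displacement.

    Zero iff the displacement is spatially constant (in particular for
    the identity transform).  Accepts a ``DeformationField`` or a raw
    displacement array/Tensor shaped ``[..., 2, H, W]``.

    With ``normalize_coords`` (the default used in training) the
    displacement is first expressed in normalized grid coordinates
    (grid extent = 2, i.e. ``u_r * 2/(H-1)``, ``u_c * 2/(W-1)``), the
    convention under which the default weights ``alpha = beta = 10^4``
    give an O(1) penalty; ``normalize_coords=False`` differences the
    raw voxel-unit displacement.
    """
    u = _displacement(phi)
    H, W = u.shape[-2], u.shape[-1]
    if H < 2 or W < 2:
        raise ValueError(f"field must be at least 2x2, got {H}x{W}")
    if normalize_coords:
        scale = np.array([2.0 / (H - 1), 2.0 / (W - 1)], dtype=np.float32)
        u = u * scale.reshape(2, 1, 1)
    n_fields = 1
    for s in u.shape[:-3]:
        n_fields *= s
    dr = u[..., 1:, :] - u[..., :-1, :]
    dc = u[..., :, 1:] - u[..., :, :-1]
    total = (dr * dr).sum() + (dc * dc).sum()
    return total * (1.0 / (H * W * n_fields))


def total_loss(Y, S, phi_ft, phi_bulk=None, weights: LossWeights | None = None):
    """Weighted sum ``dice + alpha*grad(ft) + beta*grad(bulk)``.

    The bulk term is dropped when ``phi_bulk`` is None (single-branch
    configuration).  Exactly linear in ``alpha`` and ``beta``.
    """
    if weights is None:
        weights = LossWeights()
    loss = dice_loss(Y, S) + weights.alpha * grad_loss(phi_ft)
    if phi_bulk is not None:
        loss = loss + weights.beta * grad_loss(phi_bulk)
    return loss
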