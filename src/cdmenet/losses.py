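"""Objective terms: masked cross-entropy, density-difference loss, density MSE.

All losses return plain floats; pass ``with_grad=True`` to also get the
analytic gradient with respect to the network outputs (level probabilities or
the raw density map), which the training loop feeds into backpropagation.
Targets are constants — no gradient flows through ground truth or
pseudo-labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .density import DensityMap, LevelTargets
from .network import PredictorOutputs

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "cross_entropy_loss",
    "cosine_similarity",
    "density_difference_loss",
    "mse_density_loss",
    "compose_losses",
]

logger = logging.getLogger(__name__)

_TINY = 1e-30  # guards 0/0 in unit-vector directions


@dataclass(frozen=True)
class LossWeights:
    """λ1, λ2 weight CE and DD on labeled images; λ3, λ4 on unlabeled ones."""

    lambda1: float = 0.01
    lambda2: float = 1.0
    lambda3: float = 0.01
    lambda4: float = 1.0
    epsilon: float = 1e-8  # cosine-similarity stabiliser

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3, self.lambda4) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class LossBreakdown:
    mse: float = 0.0
    ce: float = 0.0
    dd: float = 0.0
    labeled_total: float = 0.0
    unlabeled_total: float = 0.0
    total: float = 0.0


def cross_entropy_loss(
    outputs: PredictorOutputs,
    targets: LevelTargets,
    clip: float = 1e-7,
    normalize_pixels: bool = False,
    with_grad: bool = False,
):
    """Binary cross-entropy between level probabilities and level targets.

    Computed per pixel and per level, masked by the target validity map,
    summed over valid pixels and averaged over the k levels — a pixel sum,
    on the same scale as the density MSE and the column-summed
    density-difference loss.  ``normalize_pixels=True`` additionally divides
    by the number of valid pixels (a per-pixel mean, for diagnostics).
    Probabilities are clipped away from {0, 1} before the logarithms.
    """
    p = np.asarray(outputs.level_probs)
    t = targets.maps
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {t.shape}")
    valid = targets.validity
    n_valid = valid.sum()
    k = p.shape[0]
    if n_valid == 0:
        logger.debug("cross_entropy_loss: no valid pixels; returning 0")
        return (0.0, np.zeros_like(p)) if with_grad else 0.0
    denom = k * n_valid if normalize_pixels else k
    pc = np.clip(p, clip, 1.0 - clip)
    bce = -(t * np.log(pc) + (1.0 - t) * np.log1p(-pc))
    loss = float((bce * valid[None]).sum() / denom)
    if not with_grad:
        return loss
    grad = (pc - t) / (pc * (1.0 - pc)) * valid[None] / denom
    grad[(p < clip) | (p > 1.0 - clip)] = 0.0  # clipped region is flat
    return loss, grad


def cosine_similarity(f1: np.ndarray, f2: np.ndarray, epsilon: float = 1e-8) -> float:
    """dot(f1, f2) / (|f1|·|f2| + ε); 0 when either vector vanishes."""
    f1 = np.asarray(f1, dtype=np.float64).ravel()
    f2 = np.asarray(f2, dtype=np.float64).ravel()
    if f1.shape != f2.shape:
        raise ValueError(f"length mismatch: {f1.shape} vs {f2.shape}")
    return float(f1 @ f2 / (np.linalg.norm(f1) * np.linalg.norm(f2) + epsilon))


def density_difference_loss(
    outputs: PredictorOutputs,
    targets: LevelTargets,
    epsilon: float = 1e-8,
    extract: str = "columns",
    with_grad: bool = False,
):
    """Cosine-similarity loss separating the k density levels' features.

    Feature vectors are the columns of the predicted and target level maps
    (``extract="rows"`` flips the axis for sensitivity checks).  The pulling
    term averages matched-level similarities over k and enters negatively;
    the pushing term averages cross-level similarities over the k(k-1) ordered
    pairs and enters positively:

        L_DD = -(1/k) Σ_i Σ_w S(f'_iw, f_iw)
               + (1/(k(k-1))) Σ_i Σ_{j≠i} Σ_w S(f'_iw, f_jw)

    Sums over the column index w are not width-normalised, so the loss scales
    with map width.  For pseudo-label targets the invalid pixels are zeroed in
    the target columns before the similarities.
    """
    p = np.asarray(outputs.level_probs, dtype=np.float64)
    t = targets.maps * targets.validity[None]
    if p.shape != t.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {t.shape}")
    k = p.shape[0]
    if k < 2:
        raise ValueError("density difference loss needs k >= 2 levels")
    if extract not in ("columns", "rows"):
        raise ValueError("extract must be 'columns' or 'rows'")
    if extract == "rows":
        p = p.transpose(0, 2, 1)
        t = t.transpose(0, 2, 1)

    # vectors run along axis 1 (length H); w indexes columns
    dots = np.einsum("ihw,jhw->ijw", p, t)  # (k, k, W)
    n_p = np.linalg.norm(p, axis=1)  # (k, W)
    n_t = np.linalg.norm(t, axis=1)  # (k, W)
    den = n_p[:, None, :] * n_t[None, :, :] + epsilon
    sim = dots / den

    coeff = np.full((k, k), 1.0 / (k * (k - 1)))
    np.fill_diagonal(coeff, -1.0 / k)
    loss = float(np.einsum("ij,ijw->", coeff, sim))
    if not with_grad:
        return loss

    # dS/df'_i = f_j/den - S * (|f_j|/den) * (f'_i/|f'_i|)
    unit_p = p / np.maximum(n_p, _TINY)[:, None, :]
    grad = np.einsum("ijw,jhw->ihw", coeff[:, :, None] / den, t)
    s2 = (coeff[:, :, None] * sim * n_t[None, :, :] / den).sum(axis=1)  # (k, W)
    grad -= unit_p * s2[:, None, :]
    if extract == "rows":
        grad = grad.transpose(0, 2, 1)
    return loss, grad


def mse_density_loss(
    predicted: DensityMap, target: DensityMap, n_images: int = 1, with_grad: bool = False
):
    """Squared L2 distance between density maps, summed over pixels.

    The per-image squared norms are averaged over the ``n_images`` in the
    batch; with the batch-size-1 protocol the loss is the plain pixel sum.
    """
    a, b = predicted.values, target.values
    if a.shape != b.shape or predicted.resolution_divisor != target.resolution_divisor:
        raise ValueError(
            f"density maps disagree: {a.shape}@/{predicted.resolution_divisor} vs "
            f"{b.shape}@/{target.resolution_divisor}"
        )
    diff = a - b
    loss = float((diff**2).sum() / n_images)
    if not with_grad:
        return loss
    return loss, 2.0 * diff / n_images


def compose_losses(
    *,
    ce: float,
    dd: float,
    mse: float | None = None,
    weights: LossWeights = LossWeights(),
    image_is_labeled: bool,
) -> LossBreakdown:
    """Combine the terms into the labeled / unlabeled / total objective.

    Labeled images optimise MSE + λ1·CE + λ2·DD; unlabeled images only the
    auxiliary terms λ3·CE + λ4·DD — they never train the density regressor,
    so supplying a density (MSE) term for an unlabeled image is a contract
    violation.
    """
    if image_is_labeled:
        if mse is None:
            raise ValueError("labeled images require a density MSE term")
        labeled_total = mse + weights.lambda1 * ce + weights.lambda2 * dd
        return LossBreakdown(
            mse=mse, ce=ce, dd=dd,
            labeled_total=labeled_total, unlabeled_total=0.0, total=labeled_total,
        )
    if mse is not None:
        raise ValueError("unlabeled images must not carry a density target")
    unlabeled_total = weights.lambda3 * ce + weights.lambda4 * dd
    return LossBreakdown(
        mse=0.0, ce=ce, dd=dd,
        labeled_total=0.0, unlabeled_total=unlabeled_total, total=unlabeled_total,
    )
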