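"""Scikit-learn style estimator wrapping the semi-supervised counting model.

``CDMECounter`` is a regressor from RGB images to object counts.  ``fit``
takes a list of images and a parallel list of per-image annotations, where an
entry of ``None`` marks an unlabeled image — the semi-supervised setting is
expressed directly in ``y``.  ``predict`` returns per-image counts and
``score`` the coefficient of determination over counts, so the estimator
composes with sklearn model selection.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .density import (
    DensityMap,
    PointSet,
    downsample_sum,
    make_density_map,
    compute_thresholds,
)
from .evaluation import compute_metrics, count_from_density
from .losses import LossWeights
from .network import NetworkConfig, CDMENet, build_network
from .pseudolabels import PseudoLabelConfig
from .training import TrainConfig, train

__all__ = ["CDMECounter"]


def _as_pointset(y, image: np.ndarray, idx: int) -> PointSet:
    if isinstance(y, PointSet):
        return y
    h, w = np.asarray(image).shape[:2]
    return PointSet(f"image-{idx}", w, h, np.asarray(y, dtype=float).reshape(-1, 2))


class CDMECounter(BaseEstimator, RegressorMixin):
    """Semi-supervised density-map counter with mutual-exclusion pseudo-labels.

    Parameters
    ----------
    sigma : float
        Gaussian kernel width (pixels) of the ground-truth density maps.
    quantile_positions : tuple of float
        Quantiles of the pooled nonzero density values defining the level
        thresholds; ``len - 1`` density levels / auxiliary predictors.
    t_p : float
        Pseudo-label confidence: a level probability must strictly exceed it.
    lambda1, lambda2, lambda3, lambda4 : float
        Loss weights for CE and density-difference terms on labeled
        (λ1, λ2) and unlabeled (λ3, λ4) images.
    width_scale : float
        Channel-width multiplier of the network in (0, 1]; 1 is the full
        architecture, small values give CPU-friendly tiny variants.
    epochs, initial_lr, lr_halving_period, crop_size, flip_probability
        Training protocol (see TrainConfig).
    use_unlabeled : bool
        If False, unlabeled images in ``y`` are ignored (labels-only
        ablation).
    clip_negative : bool
        Floor predicted density at zero before summing counts.
    random_state : int
        Seeds parameter initialisation, shuffling and augmentation.

    Attributes
    ----------
    model_ : CDMENet
        The fitted network.
    thresholds_ : ThresholdSet
        Density-level thresholds frozen from the labeled images.
    train_state_ : TrainState
        Loss history, best validation MAE, checkpoint path.
    """

    def __init__(
        self,
        sigma: float = 15.0,
        quantile_positions: tuple = (0.0, 0.33, 0.66, 1.0),
        t_p: float = 0.8,
        lambda1: float = 0.01,
        lambda2: float = 1.0,
        lambda3: float = 0.01,
        lambda4: float = 1.0,
        width_scale: float = 1.0,
        dilation_rate: int = 2,
        epochs: int = 120,
        initial_lr: float = 1e-6,
        lr_halving_period: int = 30,
        crop_size: tuple = (1296, 864),
        flip_probability: float = 0.5,
        use_unlabeled: bool = True,
        clip_negative: bool = False,
        random_state: int = 0,
    ):
        self.sigma = sigma
        self.quantile_positions = quantile_positions
        self.t_p = t_p
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.lambda4 = lambda4
        self.width_scale = width_scale
        self.dilation_rate = dilation_rate
        self.epochs = epochs
        self.initial_lr = initial_lr
        self.lr_halving_period = lr_halving_period
        self.crop_size = crop_size
        self.flip_probability = flip_probability
        self.use_unlabeled = use_unlabeled
        self.clip_negative = clip_negative
        self.random_state = random_state

    # ------------------------------------------------------------------- fit
    def fit(self, X: Sequence[np.ndarray], y: Sequence,
            val_set=None, checkpoint_path=None, log_path=None):
        """Train on images ``X`` with annotations ``y`` (None = unlabeled).

        ``val_set`` is an optional list of (image, PointSet) pairs scored for
        MAE each epoch; the best-MAE parameters are retained.
        """
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        labeled, unlabeled = [], []
        for i, (img, ann) in enumerate(zip(X, y)):
            if ann is None:
                unlabeled.append(np.asarray(img))
            else:
                labeled.append((np.asarray(img), _as_pointset(ann, img, i)))
        if not labeled:
            raise ValueError("at least one labeled image is required")
        if not self.use_unlabeled:
            unlabeled = []

        net_cfg = NetworkConfig(
            n_levels=len(self.quantile_positions) - 1,
            width_scale=self.width_scale,
            dilation_rate=self.dilation_rate,
        )
        self.model_ = build_network(net_cfg, seed=self.random_state)
        factor = net_cfg.downsample_factor
        # thresholds from labeled images only, at the network's resolution
        gt_maps = [
            downsample_sum(make_density_map(p, sigma=self.sigma), factor)
            for _, p in labeled
        ]
        self.thresholds_ = compute_thresholds(gt_maps, self.quantile_positions)

        train_cfg = TrainConfig(
            epochs=self.epochs,
            initial_lr=self.initial_lr,
            lr_halving_period=self.lr_halving_period,
            crop_size=tuple(self.crop_size),
            flip_probability=self.flip_probability,
            labeled_ratio=len(labeled) / max(len(labeled) + len(unlabeled), 1),
            seed=self.random_state,
            sigma=self.sigma,
        )
        weights = LossWeights(self.lambda1, self.lambda2, self.lambda3, self.lambda4)
        self.train_state_ = train(
            self.model_,
            labeled,
            unlabeled,
            self.thresholds_,
            weights=weights,
            cfg=train_cfg,
            pseudo_cfg=PseudoLabelConfig(self.t_p),
            val_set=val_set,
            checkpoint_path=checkpoint_path,
            log_path=log_path,
        )
        self.n_levels_ = net_cfg.n_levels
        return self

    # --------------------------------------------------------------- predict
    def predict_density(self, X: Sequence[np.ndarray]) -> list[DensityMap]:
        """Predicted 1/8-resolution density maps for a list of images."""
        self._check_fitted()
        return [self.model_.forward(np.asarray(img)).density for img in X]

    def predict(self, X: Sequence[np.ndarray]) -> np.ndarray:
        """Predicted object counts (density-map sums)."""
        return np.array(
            [count_from_density(d, self.clip_negative) for d in self.predict_density(X)]
        )

    def score(self, X: Sequence[np.ndarray], y: Sequence) -> float:
        """Coefficient of determination over per-image counts."""
        truths = [
            p.count() if isinstance(p, PointSet)
            else (len(np.asarray(p).reshape(-1, 2)) if np.ndim(p) > 0 else float(p))
            for p in y
        ]
        m = compute_metrics(truths, self.predict(X))
        if m.r2 is None:
            raise ValueError("R^2 undefined: all true counts identical")
        return m.r2

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("this CDMECounter instance is not fitted yet")
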