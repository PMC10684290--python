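"""Semi-supervised training loop: mixed streaming, augmentation, scheduling.

Each epoch shuffles the union of labeled and unlabeled images and visits every
image once (batch size 1).  Labeled steps optimise density MSE plus the
weighted auxiliary terms against ground-truth level targets; unlabeled steps
optimise only the auxiliary terms against mutual-exclusion pseudo-labels
regenerated from the current predictions, so the density regressor never sees
unlabeled supervision.  The learning rate starts at ``initial_lr`` and is
halved every ``lr_halving_period`` epochs; Adam with library defaults does the
updates.  Runs are fully reproducible under a fixed seed on one device.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .density import (
    PointSet,
    ThresholdSet,
    downsample_sum,
    make_density_map,
    make_level_targets,
)
from .evaluation import count_from_density
from .losses import (
    LossWeights,
    compose_losses,
    cross_entropy_loss,
    density_difference_loss,
    mse_density_loss,
)
from .network import CDMENet, save_checkpoint
from .pseudolabels import PseudoLabelConfig, generate_pseudo_labels
from .nn import Adam

__all__ = ["TrainConfig", "TrainState", "split_dataset", "augment",
           "learning_rate", "train"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters.

    Defaults follow the full-scale field protocol (120 epochs, batch 1,
    Adam at 1e-6 halved every 30 epochs, 1296x864 crops, random horizontal
    flips); desk-scale runs shrink the crop, epochs and learning rate.
    """

    epochs: int = 120
    batch_size: int = 1
    initial_lr: float = 1e-6
    lr_halving_period: int = 30
    crop_size: tuple[int, int] = (1296, 864)  # (width, height)
    flip_probability: float = 0.5
    labeled_ratio: float = 0.1
    seed: int = 0
    sigma: float = 15.0
    sampling: str = "shuffled"  # or "alternating"

    def __post_init__(self) -> None:
        if not (0 < self.labeled_ratio <= 1):
            raise ValueError("labeled_ratio must lie in (0, 1]")
        if self.crop_size[0] % 8 or self.crop_size[1] % 8:
            raise ValueError("crop dimensions must be divisible by 8")
        if self.sampling not in ("shuffled", "alternating"):
            raise ValueError("sampling must be 'shuffled' or 'alternating'")


@dataclass
class TrainState:
    epoch: int = 0
    step: int = 0
    current_lr: float = 0.0
    history: list[dict] = field(default_factory=list)
    best_val_mae: float | None = None
    checkpoint_path: str | None = None


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """initial_lr halved every ``lr_halving_period`` epochs (0-based epochs)."""
    return cfg.initial_lr * 0.5 ** (epoch // cfg.lr_halving_period)


def split_dataset(
    image_ids: Sequence[str],
    ratios: tuple[int, int, int] = (3, 1, 1),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Random, seed-deterministic train/val/test partition.

    Sizes are proportional to ``ratios`` with largest-remainder rounding; the
    partition is disjoint and exhaustive.
    """
    ids = list(image_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("image ids must be unique")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    n = len(ids)
    if n < len(ratios):
        raise ValueError(f"need at least {len(ratios)} ids, got {n}")
    total = sum(ratios)
    quotas = [n * r / total for r in ratios]
    sizes = [math.floor(q) for q in quotas]
    remainders = sorted(
        range(len(ratios)), key=lambda i: (quotas[i] - sizes[i], -i), reverse=True
    )
    for i in range(n - sum(sizes)):
        sizes[remainders[i]] += 1
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    out, start = [], 0
    for s in sizes:
        out.append(perm[start : start + s])
        start += s
    return out[0], out[1], out[2]


def augment(
    image: np.ndarray,
    points: PointSet | None,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, PointSet | None]:
    """Random crop + random horizontal flip, mirrored onto the annotations.

    Points outside the crop are dropped and survivors re-referenced to the
    crop origin; a flip maps x to width-1-x.  A crop larger than the image
    falls back to a centred zero-pad (logged).
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    cw, ch = cfg.crop_size
    pts = None if points is None else points.points.copy()

    if cw > w or ch > h:
        logger.warning("crop %sx%s exceeds image %sx%s; centre-padding", cw, ch, w, h)
        pad_x, pad_y = max(0, cw - w), max(0, ch - h)
        img = np.pad(img, ((pad_y // 2, pad_y - pad_y // 2),
                           (pad_x // 2, pad_x - pad_x // 2), (0, 0)))
        if pts is not None and len(pts):
            pts = pts + np.array([pad_x // 2, pad_y // 2], dtype=float)
        h, w = img.shape[:2]

    ox = int(rng.integers(0, w - cw + 1))
    oy = int(rng.integers(0, h - ch + 1))
    img = img[oy : oy + ch, ox : ox + cw]
    if pts is not None and len(pts):
        keep = (
            (pts[:, 0] >= ox) & (pts[:, 0] < ox + cw)
            & (pts[:, 1] >= oy) & (pts[:, 1] < oy + ch)
        )
        pts = pts[keep] - np.array([ox, oy], dtype=float)

    if rng.random() < cfg.flip_probability:
        img = img[:, ::-1].copy()
        if pts is not None and len(pts):
            # fractional x in (cw-1, cw) would land just below 0; clamp in-frame
            pts[:, 0] = np.clip(cw - 1 - pts[:, 0], 0.0, cw - 1.0)

    new_points = None
    if points is not None:
        new_points = PointSet(points.image_id, cw, ch,
                              pts if pts is not None else np.empty((0, 2)))
    return img, new_points


def _ground_truth_targets(points: PointSet, thresholds: ThresholdSet, sigma: float,
                          factor: int):
    full = make_density_map(points, sigma=sigma)
    gt8 = downsample_sum(full, factor)
    return gt8, make_level_targets(gt8, thresholds)


def _validate(model: CDMENet, val_set) -> float:
    errors = []
    for image, points in val_set:
        out = model.forward(image)
        pred = count_from_density(out.density)
        truth = points.count() if isinstance(points, PointSet) else float(points)
        errors.append(abs(truth - pred))
    return float(np.mean(errors))


def train(
    model: CDMENet,
    labeled: Sequence[tuple[np.ndarray, PointSet]],
    unlabeled: Sequence[np.ndarray],
    thresholds: ThresholdSet,
    weights: LossWeights = LossWeights(),
    cfg: TrainConfig = TrainConfig(),
    pseudo_cfg: PseudoLabelConfig = PseudoLabelConfig(),
    val_set: Sequence[tuple[np.ndarray, PointSet]] | None = None,
    checkpoint_path: str | Path | None = None,
    log_path: str | Path | None = None,
) -> TrainState:
    """Run the semi-supervised loop and return the final training state.

    ``thresholds`` must come from the labeled set only (computed upstream);
    pseudo-labels for unlabeled images are rebuilt from the model's own level
    predictions at every step and treated as constants.  When ``val_set`` is
    given, validation MAE is computed each epoch and the best-MAE parameters
    are kept (checkpointed to ``checkpoint_path`` if provided).
    """
    if not labeled:
        raise ValueError("cannot train without labeled images")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    state = TrainState()
    factor = model.cfg.downsample_factor
    log_fh = open(log_path, "w") if log_path else None
    best_params = None

    items = [("labeled", i) for i in range(len(labeled))] + [
        ("unlabeled", i) for i in range(len(unlabeled))
    ]
    try:
        for epoch in range(cfg.epochs):
            lr = learning_rate(epoch, cfg)
            opt.lr = lr
            if cfg.sampling == "shuffled":
                order = [items[i] for i in rng.permutation(len(items))]
            else:  # alternate labeled/unlabeled as far as both last
                lab = [it for it in items if it[0] == "labeled"]
                unl = [it for it in items if it[0] == "unlabeled"]
                rng.shuffle(lab), rng.shuffle(unl)
                order = [x for pair in zip(lab, unl) for x in pair]
                order += lab[len(unl):] + unl[len(lab):]

            sums = {"mse": 0.0, "ce": 0.0, "dd": 0.0, "total": 0.0}
            n_lab = 0
            for kind, idx in order:
                if kind == "labeled":
                    image, points = labeled[idx]
                    img_c, pts_c = augment(image, points, cfg, rng)
                    gt8, targets = _ground_truth_targets(
                        pts_c, thresholds, cfg.sigma, factor
                    )
                    out = model.forward(img_c)
                    mse, g_mse = mse_density_loss(out.density, gt8, with_grad=True)
                    ce, g_ce = cross_entropy_loss(out, targets, with_grad=True)
                    dd, g_dd = density_difference_loss(
                        out, targets, weights.epsilon, with_grad=True
                    )
                    bd = compose_losses(ce=ce, dd=dd, mse=mse, weights=weights,
                                        image_is_labeled=True)
                    g_probs = weights.lambda1 * g_ce + weights.lambda2 * g_dd
                    model.zero_grad()
                    model.backward(g_mse, g_probs)
                    sums["mse"] += mse
                    n_lab += 1
                else:
                    img_c, _ = augment(unlabeled[idx], None, cfg, rng)
                    out = model.forward(img_c)
                    pseudo = generate_pseudo_labels(out, pseudo_cfg)
                    ce, g_ce = cross_entropy_loss(out, pseudo, with_grad=True)
                    dd, g_dd = density_difference_loss(
                        out, pseudo, weights.epsilon, with_grad=True
                    )
                    bd = compose_losses(ce=ce, dd=dd, weights=weights,
                                        image_is_labeled=False)
                    g_probs = weights.lambda3 * g_ce + weights.lambda4 * g_dd
                    model.zero_grad()
                    model.backward(None, g_probs)
                # a step with no supervision (e.g. an unlabeled image whose
                # pseudo-labels are entirely excluded) must be a no-op, not a
                # stale-momentum update
                if any(np.any(p.grad) for p in model.parameters()):
                    opt.step()
                sums["ce"] += bd.ce
                sums["dd"] += bd.dd
                sums["total"] += bd.total
                state.step += 1
                if log_fh:
                    log_fh.write(json.dumps({
                        "epoch": epoch, "step": state.step, "kind": kind, "lr": lr,
                        "mse": bd.mse, "ce": bd.ce, "dd": bd.dd, "total": bd.total,
                    }) + "\n")

            record = {
                "epoch": epoch,
                "lr": lr,
                "mean_labeled_mse": sums["mse"] / max(n_lab, 1),
                "mean_ce": sums["ce"] / len(order),
                "mean_dd": sums["dd"] / len(order),
                "mean_total": sums["total"] / len(order),
            }
            if val_set is not None:
                val_mae = _validate(model, val_set)
                record["val_mae"] = val_mae
                if state.best_val_mae is None or val_mae < state.best_val_mae:
                    state.best_val_mae = val_mae
                    best_params = [p.value.copy() for p in model.parameters()]
                    if checkpoint_path is not None:
                        save_checkpoint(checkpoint_path, model, thresholds)
                        state.checkpoint_path = str(checkpoint_path)
            state.history.append(record)
            state.epoch = epoch
            state.current_lr = lr
    finally:
        if log_fh:
            log_fh.close()

    # restore the best-validation parameters (model selection)
    if best_params is not None:
        for p, v in zip(model.parameters(), best_params):
            p.value = v
    return state
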