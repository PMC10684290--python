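"""Density-mutual-exclusion pseudo-labels for unlabeled images.

A pixel's density value belongs to exactly one density level, so the k level
predictors should never fire together.  Pseudo-labels are built from the
model's own level probabilities: a predictor "fires" on a pixel when its
probability strictly exceeds the confidence threshold t_p.  A single firing
predictor yields a foreground pseudo-label for that level; multiple firings
contradict the mutual-exclusion prior and the pixel is invalidated (excluded
from supervision); by default a pixel with no firing predictor carries no
supervision either, so only confident, non-contradictory predictions teach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import LevelTargets
from .network import PredictorOutputs

__all__ = ["PseudoLabelConfig", "generate_pseudo_labels", "exclusion_stats"]


@dataclass(frozen=True)
class PseudoLabelConfig:
    """Pseudo-label generation parameters.

    ``t_p`` is the prediction confidence a level probability must strictly
    exceed to fire.  ``zero_fire`` selects what a pixel where *no* predictor
    fires contributes: ``"exclude"`` (default) removes it from supervision —
    only confidently predicted pixels teach — while ``"background"`` keeps it
    as a valid all-zero target.  The background reading suppresses the level
    predictors' confidence early in training (their own cautious predictions
    push every probability toward zero, so no pixel ever crosses t_p and the
    mutual-exclusion mechanism never engages); exclusion lets confidence
    emerge from the labeled images and reinforces it on the unlabeled ones.
    """

    t_p: float = 0.8
    zero_fire: str = "exclude"

    def __post_init__(self) -> None:
        if not (0.0 < self.t_p < 1.0):
            raise ValueError(f"t_p must lie in (0, 1), got {self.t_p}")
        if self.zero_fire not in ("exclude", "background"):
            raise ValueError("zero_fire must be 'exclude' or 'background'")


def generate_pseudo_labels(
    outputs: PredictorOutputs, cfg: PseudoLabelConfig = PseudoLabelConfig()
) -> LevelTargets:
    """Correct the raw level predictions into mutually exclusive pseudo-labels.

    Per pixel: probabilities > t_p fire; exactly one firing assigns that level
    as foreground (validity 1); two or more firings contradict the
    mutual-exclusion prior and mark the pixel invalid (validity 0, no level);
    a pixel with no firing is excluded too (or kept as valid background under
    ``zero_fire="background"``).  The result is treated as a constant — no
    gradient flows through it.
    """
    probs = np.asarray(outputs.level_probs)
    if probs.ndim != 3:
        raise ValueError(f"expected (k, H, W) level probabilities, got {probs.shape}")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("level probabilities must lie in [0, 1]")
    fired = probs > cfg.t_p  # strict: probability exactly t_p does not fire
    n_fired = fired.sum(axis=0)
    maps = (fired & (n_fired == 1)).astype(np.float64)
    if cfg.zero_fire == "exclude":
        validity = (n_fired == 1).astype(np.float64)
    else:
        validity = (n_fired <= 1).astype(np.float64)
    return LevelTargets(
        maps,
        validity=validity,
        resolution_divisor=outputs.density.resolution_divisor,
        source="pseudo_label",
    )


def exclusion_stats(targets: LevelTargets) -> dict:
    """Monitoring summary: per-level foreground counts and invalid fraction."""
    if targets.source != "pseudo_label":
        raise ValueError("exclusion_stats expects pseudo-label targets")
    n_pixels = targets.validity.size
    return {
        "n_pixels": int(n_pixels),
        "foreground_per_level": [int(m.sum()) for m in targets.maps],
        "invalid_fraction": float((targets.validity == 0).sum() / n_pixels),
        "background_fraction": float(
            ((targets.validity == 1) & (targets.maps.sum(axis=0) == 0)).sum() / n_pixels
        ),
    }
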