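"""Ground-truth density maps and density-level targets from point annotations.

Each annotated object centre contributes one unit-integral isotropic Gaussian
bump to the density map, so the map integrates to the object count.  Density
*levels* partition the strictly positive density values into ``k`` intervals
whose boundaries are quantiles of the pooled nonzero ground-truth values of
the labelled images; the binary per-level masks are the targets of the
auxiliary segmentation predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PointSet",
    "DensityMap",
    "ThresholdSet",
    "LevelTargets",
    "make_density_map",
    "downsample_sum",
    "compute_thresholds",
    "make_level_targets",
]

#: default Gaussian kernel width (pixels) for ground-truth density maps
DEFAULT_SIGMA = 15.0

#: default quantile positions of the pooled nonzero density values;
#: c = 4 thresholds define k = 3 density levels
DEFAULT_QUANTILE_POSITIONS = (0.0, 0.33, 0.66, 1.0)


@dataclass(frozen=True)
class PointSet:
    """Per-image object-centre annotations (0-based, pixel-centre convention)."""

    image_id: str
    width: int
    height: int
    points: np.ndarray  # (N, 2) float array of (x, y)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if len(pts):
            x, y = pts[:, 0], pts[:, 1]
            bad = (x < 0) | (x >= self.width) | (y < 0) | (y >= self.height)
            if bad.any():
                offenders = pts[bad].tolist()
                raise ValueError(
                    f"{self.image_id}: {bad.sum()} point(s) outside the "
                    f"{self.width}x{self.height} image: {offenders[:5]}"
                )

    def count(self) -> int:
        return len(self.points)


@dataclass
class DensityMap:
    """Non-negative 2-D grid of object density (objects per pixel).

    ``resolution_divisor`` records the spatial scale relative to the source
    image: 1 for full-resolution ground truth, 8 for maps at the network's
    output resolution.  Predicted maps from the raw regression head may carry
    small negative values; ground-truth constructors guarantee nonnegativity.
    """

    values: np.ndarray
    resolution_divisor: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("density map must be 2-D")
        if self.resolution_divisor < 1:
            raise ValueError("resolution_divisor must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sum(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered density thresholds at quantiles of the pooled nonzero values.

    ``c`` thresholds t_1 <= ... <= t_c define ``n_levels = c - 1`` half-open
    density intervals; the lowest interval opens at 0 so every positive-density
    pixel belongs to exactly one level.
    """

    quantile_positions: tuple[float, ...]
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.quantile_positions) != len(self.thresholds):
            raise ValueError("positions and thresholds must align")
        if self.n_levels < 2:
            raise ValueError(
                "density mutual exclusion needs at least 2 levels "
                f"(got {self.n_levels})"
            )
        if any(b < a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be non-decreasing")

    @property
    def n_levels(self) -> int:
        return len(self.thresholds) - 1

    def level_bounds(self) -> list[tuple[float, float]]:
        """(lower, upper] interval per level; level 1 opens at 0."""
        t = self.thresholds
        return [(0.0 if j == 0 else t[j], t[j + 1]) for j in range(self.n_levels)]


@dataclass
class LevelTargets:
    """k binary level masks plus a per-pixel validity mask.

    Holds both ground-truth segmentation targets (validity all ones) and
    mutual-exclusion-corrected pseudo-labels (invalid pixels excluded from
    supervision).  At most one level mask is set per pixel by construction.
    """

    maps: np.ndarray  # (k, H, W) in {0, 1}
    validity: np.ndarray  # (H, W) in {0, 1}
    resolution_divisor: int = 8
    source: str = "ground_truth"  # or "pseudo_label"

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        self.validity = np.asarray(self.validity, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("maps must be (k, H, W)")
        if self.validity.shape != self.maps.shape[1:]:
            raise ValueError("validity shape must match the level maps")
        if (self.maps.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("level masks must be mutually exclusive")

    @property
    def n_levels(self) -> int:
        return self.maps.shape[0]


def make_density_map(
    points: PointSet, sigma: float = DEFAULT_SIGMA, truncate: float = 4.0
) -> DensityMap:
    """Blur point annotations into a full-resolution density map.

    Each point contributes an isotropic Gaussian of width ``sigma`` sampled at
    pixel centres and normalised to unit mass over its (untruncated) support,
    then clipped at the image border without renormalisation — border-adjacent
    annotations therefore contribute slightly less than one count.

    Parameters
    ----------
    points
        Annotations; coordinates may be fractional.
    sigma
        Gaussian kernel width in pixels (> 0).
    truncate
        Kernel support radius in units of sigma.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    h, w = points.height, points.width
    out = np.zeros((h, w), dtype=np.float64)
    radius = int(math.ceil(truncate * sigma))
    for x, y in points.points:
        # full (border-free) kernel window, used for normalisation
        cx0, cy0 = int(math.floor(x)) - radius, int(math.floor(y)) - radius
        xs = np.arange(cx0, cx0 + 2 * radius + 1, dtype=np.float64)
        ys = np.arange(cy0, cy0 + 2 * radius + 1, dtype=np.float64)
        gx = np.exp(-((xs - x) ** 2) / (2.0 * sigma**2))
        gy = np.exp(-((ys - y) ** 2) / (2.0 * sigma**2))
        kern = np.outer(gy, gx)
        kern /= kern.sum()
        # clip to the image; mass outside the border is dropped
        y0, y1 = max(0, cy0), min(h, cy0 + 2 * radius + 1)
        x0, x1 = max(0, cx0), min(w, cx0 + 2 * radius + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        out[y0:y1, x0:x1] += kern[y0 - cy0 : y1 - cy0, x0 - cx0 : x1 - cx0]
    return DensityMap(out, resolution_divisor=1)


def downsample_sum(d: DensityMap, factor: int) -> DensityMap:
    """Sum-preserving block reduction by ``factor`` along both axes.

    Reconciles full-resolution ground truth with the network's 1/8-resolution
    output without changing the integral (count) of the map.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return DensityMap(d.values.copy(), d.resolution_divisor)
    h, w = d.values.shape
    if h % factor or w % factor:
        raise ValueError(
            f"map shape {(h, w)} not divisible by factor {factor}; pad or crop first"
        )
    v = d.values.reshape(h // factor, factor, w // factor, factor).sum(axis=(1, 3))
    return DensityMap(v, d.resolution_divisor * factor)


def compute_thresholds(
    labeled_maps: Sequence[DensityMap],
    quantile_positions: Sequence[float] = DEFAULT_QUANTILE_POSITIONS,
) -> ThresholdSet:
    """Derive density-level thresholds from labelled ground-truth maps.

    All strictly positive density values across the labelled maps are pooled
    into an ascending sequence {d_p} of length T; the threshold at quantile
    position S is the value at 1-based index clamp(ceil(S*T), 1, T), so S = 0
    maps to the smallest nonzero value and S = 1 to the largest.
    """
    pos = [float(s) for s in quantile_positions]
    if sorted(pos) != pos or any(s < 0 or s > 1 for s in pos):
        raise ValueError("quantile positions must be sorted within [0, 1]")
    if len(pos) < 3:
        raise ValueError("need at least 3 quantile positions (>= 2 levels)")
    if not labeled_maps:
        raise ValueError("no labelled maps supplied")
    vals = np.concatenate([m.values.ravel() for m in labeled_maps])
    d_p = np.sort(vals[vals > 0])
    t_len = len(d_p)
    if t_len == 0:
        raise ValueError("labelled maps contain no nonzero density values")
    idx = [min(max(math.ceil(s * t_len), 1), t_len) for s in pos]
    thresholds = tuple(float(d_p[i - 1]) for i in idx)
    return ThresholdSet(tuple(pos), thresholds)


def make_level_targets(d: DensityMap, th: ThresholdSet) -> LevelTargets:
    """Binary ground-truth level masks for a density map.

    Level j (1-based) is set where lower_j < D <= t_{j+1}, with lower_1 = 0 and
    lower_j = t_j otherwise, so every pixel lands in at most one level; ties on
    the closed upper bound resolve to the lower level (foreground).  Pixels
    above the top threshold or at exactly zero density belong to no level.
    """
    dv = d.values
    k = th.n_levels
    maps = np.zeros((k,) + dv.shape, dtype=np.float64)
    for j, (lower, upper) in enumerate(th.level_bounds()):
        maps[j] = ((dv > lower) & (dv <= upper)).astype(np.float64)
    return LevelTargets(
        maps,
        validity=np.ones(dv.shape, dtype=np.float64),
        resolution_divisor=d.resolution_divisor,
        source="ground_truth",
    )
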