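"""Seeded generator of berry-cluster scenes with point annotations.

Scenes follow a Thomas-like cluster process: cluster centres fall uniformly in
the frame, berries scatter around each centre with Gaussian spread, and each
berry is rendered as a shaded, colour-jittered disk over a textured green
background.  The generator targets the statistical preconditions of
density-map counting — dense clusters, several occupied density levels,
occlusion — not photo-realism.  Per-image counts are rejection-sampled into a
target range, a scaled-down analogue of field images carrying hundreds to
thousands of berries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .density import PointSet

__all__ = ["SceneSpec", "generate_scene", "generate_dataset", "load_manifest"]


@dataclass(frozen=True)
class SceneSpec:
    """Statistical description of a synthetic berry scene.

    Defaults draw 30-200 berries on a 256x256 frame (a ~1/8-scale analogue of
    field images with 206-1,585 berries); sizes must be divisible by 8 so the
    network needs no padding.
    """

    width: int = 256
    height: int = 256
    n_clusters: tuple[int, int] = (6, 14)  # inclusive range
    berries_per_cluster: float = 12.0  # Poisson mean
    cluster_spread: float = 10.0  # sigma of berry offsets, pixels
    berry_radius: tuple[float, float] = (3.0, 6.0)
    #: per-image berry colour families, emulating cultivar variation
    #: (dark purple, red, and green/white berries)
    berry_palette: tuple[tuple[int, int, int], ...] = (
        (88, 24, 69),
        (130, 40, 45),
        (120, 150, 80),
    )
    color_jitter: int = 25
    #: per-image global illumination gain range (field lighting variation)
    illumination: tuple[float, float] = (0.6, 1.3)
    background_amplitude: float = 18.0
    occlusion: bool = True
    count_range: tuple[int, int] = (30, 200)
    max_retries: int = 60

    def __post_init__(self) -> None:
        if self.width % 8 or self.height % 8:
            raise ValueError("scene sides must be divisible by 8")
        if self.n_clusters[1] < self.n_clusters[0]:
            raise ValueError("empty n_clusters range")
        if self.berry_radius[0] < 1.0:
            raise ValueError("berry radius must be >= 1 pixel")
        if self.count_range[1] < self.count_range[0]:
            raise ValueError("empty count range")


def _render_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    base = np.array([70.0, 110.0, 60.0])  # leafy green
    noise = rng.normal(0.0, 1.0, size=(spec.height, spec.width, 3))
    texture = gaussian_filter(noise, sigma=(6, 6, 0)) * spec.background_amplitude * 4
    return np.clip(base[None, None] + texture, 0, 255)


def _sample_points(spec: SceneSpec, rng: np.random.Generator):
    n_clusters = int(rng.integers(spec.n_clusters[0], spec.n_clusters[1] + 1))
    margin = spec.berry_radius[1]
    pts = []
    for _ in range(n_clusters):
        cx = rng.uniform(0, spec.width)
        cy = rng.uniform(0, spec.height)
        n_berries = rng.poisson(spec.berries_per_cluster)
        offsets = rng.normal(0.0, spec.cluster_spread, size=(n_berries, 2))
        for dx, dy in offsets:
            x, y = cx + dx, cy + dy
            if margin <= x < spec.width - margin and margin <= y < spec.height - margin:
                pts.append((x, y))
    return pts


def _render_berries(img: np.ndarray, pts, spec: SceneSpec, rng: np.random.Generator) -> None:
    h, w = img.shape[:2]
    # sort by y so lower berries paint over upper ones, mimicking occlusion
    order = np.argsort([p[1] for p in pts]) if spec.occlusion else np.arange(len(pts))
    radii = rng.uniform(*spec.berry_radius, size=len(pts))
    jitters = rng.integers(-spec.color_jitter, spec.color_jitter + 1, size=(len(pts), 3))
    base_color = np.array(spec.berry_palette[rng.integers(len(spec.berry_palette))])
    for idx in order:
        x, y = pts[idx]
        r = radii[idx]
        color = np.clip(base_color + jitters[idx], 0, 255).astype(float)
        x0, x1 = int(np.floor(x - r - 1)), int(np.ceil(x + r + 2))
        y0, y1 = int(np.floor(y - r - 1)), int(np.ceil(y + r + 2))
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(w, x1), min(h, y1)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        d2 = (xs - x) ** 2 + (ys - y) ** 2
        inside = d2 <= r**2
        # radial shading with a specular offset toward the upper-left
        shade = 1.15 - 0.55 * np.sqrt(np.clip(d2, 0, None)) / max(r, 1.0)
        patch = img[y0:y1, x0:x1]
        patch[inside] = np.clip(color[None, :] * shade[inside][:, None], 0, 255)


def generate_scene(spec: SceneSpec, seed: int) -> tuple[np.ndarray, PointSet]:
    """Render one scene; deterministic per (spec, seed).

    Counts are rejection-resampled into ``spec.count_range``; unreachable
    ranges raise after ``spec.max_retries`` attempts.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.count_range
    for _ in range(spec.max_retries):
        pts = _sample_points(spec, rng)
        if lo <= len(pts) <= hi:
            img = _render_background(spec, rng)
            _render_berries(img, pts, spec, rng)
            img *= rng.uniform(*spec.illumination)
            img = np.clip(img, 0, 255)
            points = PointSet(
                image_id=f"scene-{seed}",
                width=spec.width,
                height=spec.height,
                points=np.array(pts, dtype=float).reshape(-1, 2),
            )
            return img.astype(np.uint8), points
    raise RuntimeError(
        f"could not hit count range {spec.count_range} in {spec.max_retries} draws; "
        "the cluster rates make the range unreachable"
    )


def generate_dataset(
    spec: SceneSpec,
    n_images: int,
    labeled_fraction: float,
    seed: int,
    out_dir: str | Path,
    force: bool = False,
) -> dict:
    """Write a labeled/unlabeled synthetic dataset to disk.

    Produces PNG images, Labelme-style JSON and CSV annotations for the
    labeled subset, withholds the unlabeled subset's annotations in a
    ``heldout/`` sidecar (for post-hoc evaluation only), and records the
    partition in ``manifest.json``.  At least one image is always labeled.
    """
    if not (0 < labeled_fraction <= 1):
        raise ValueError("labeled_fraction must lie in (0, 1]")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    (out / "heldout").mkdir(exist_ok=True)

    seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2**31)
    n_labeled = max(1, int(np.floor(n_images * labeled_fraction)))
    ids, labeled_ids, unlabeled_ids = [], [], []
    from .io import write_points_csv, write_points_labelme  # local import: no cycle

    for i in range(n_images):
        image_id = f"img_{i:04d}"
        img, points = generate_scene(spec, int(seeds[i]))
        points = PointSet(image_id, spec.width, spec.height, points.points)
        Image.fromarray(img).save(out / "images" / f"{image_id}.png")
        if i < n_labeled:
            write_points_labelme(out / "annotations" / f"{image_id}.json", points)
            write_points_csv(out / "annotations" / f"{image_id}.csv", points)
            labeled_ids.append(image_id)
        else:
            write_points_labelme(out / "heldout" / f"{image_id}.json", points)
            unlabeled_ids.append(image_id)
        ids.append(image_id)

    manifest = {
        "seed": int(seed),
        "n_images": n_images,
        "labeled_fraction": labeled_fraction,
        "image_size": [spec.width, spec.height],
        "scene_spec": asdict(spec),
        "labeled": labeled_ids,
        "unlabeled": unlabeled_ids,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_manifest(dataset_dir: str | Path) -> dict:
    return json.loads((Path(dataset_dir) / "manifest.json").read_text())
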