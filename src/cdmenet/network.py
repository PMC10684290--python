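"""Counting network: VGG16-style front end, dilated layers, and two heads.

The feature extractor follows the dilated-convolution density-regression
lineage: ten 3x3 convolution layers in four stages (64, 128, 256, 512
channels, three 2x2 max-poolings interleaved) followed by two dilated 3x3
layers (rate 2, padding 2) to 512 then 256 channels, so features live at 1/8
of the input resolution.  On top of the 256-channel map sit

* a density regressor — a linear 1x1 convolution to one channel whose sum is
  the predicted count, and
* k density-level predictors — 1x1 convolutions with sigmoid, giving per-pixel
  probabilities that a pixel's density falls in level i.

``width_scale`` shrinks every channel width by a constant factor (topology
unchanged), giving "tiny" variants that train in seconds on a CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .density import DensityMap, ThresholdSet
from .nn import Adam, Conv2d, Layer, MaxPool2x2, Param, ReLU, Sequential, Sigmoid

__all__ = ["NetworkConfig", "PredictorOutputs", "CDMENet", "build_network",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_FORMAT = "cdmenet-checkpoint-v1"

#: full-width channel plan: four backbone stages then the two dilated stages
FULL_CHANNEL_PLAN = (64, 128, 256, 512, 512, 256)
#: convolution layers per backbone stage (VGG16's 2-2-3-3)
STAGE_DEPTHS = (2, 2, 3, 3)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``n_levels`` is the number k of density-level predictors;
    ``width_scale`` in (0, 1] multiplies every channel width (minimum 1);
    ``downsample_factor`` is fixed at 8 by the three pooling stages.
    """

    n_levels: int = 3
    channel_plan: tuple[int, ...] = FULL_CHANNEL_PLAN
    width_scale: float = 1.0
    dilation_rate: int = 2
    downsample_factor: int = 8

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 density levels")
        if not (0 < self.width_scale <= 1):
            raise ValueError("width_scale must lie in (0, 1]")
        if self.downsample_factor != 8:
            raise ValueError("the architecture fixes an 8x spatial reduction")
        if len(self.channel_plan) != 6:
            raise ValueError("channel_plan must list 4 stage widths + 2 dilated widths")

    def scaled_channels(self) -> list[int]:
        return [max(1, round(c * self.width_scale)) for c in self.channel_plan]


@dataclass
class PredictorOutputs:
    """Raw density prediction plus k level-probability maps at 1/8 resolution."""

    density: DensityMap  # raw head output; sign-unconstrained
    level_probs: np.ndarray  # (k, H/8, W/8) in [0, 1]


class CDMENet:
    """The counting model: shared trunk, density head, k sigmoid level heads.

    ``forward`` accepts an H x W x 3 image (uint8 or float); channels are
    scaled to [0, 1].  Sides not divisible by 8 are zero-padded on the
    right/bottom and the outputs cropped back to ceil(H/8) x ceil(W/8).
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        ch = cfg.scaled_channels()
        layers: list[Layer] = []
        in_c = 3
        for stage, depth in enumerate(STAGE_DEPTHS):
            out_c = ch[stage]
            for _ in range(depth):
                layers += [Conv2d(in_c, out_c, 3, rng), ReLU()]
                in_c = out_c
            if stage < 3:  # three halvings -> 1/8 resolution
                layers.append(MaxPool2x2())
        for out_c in ch[4:]:
            layers += [Conv2d(in_c, out_c, 3, rng, dilation=cfg.dilation_rate), ReLU()]
            in_c = out_c
        self.trunk = Sequential(layers)
        self.head_density = Conv2d(in_c, 1, 1, rng)
        self.head_levels = [Conv2d(in_c, 1, 1, rng) for _ in range(cfg.n_levels)]
        self._level_sigmoids = [Sigmoid() for _ in range(cfg.n_levels)]
        self._cache: dict | None = None

    # ------------------------------------------------------------------ params
    def parameters(self) -> list[Param]:
        ps = self.trunk.parameters() + self.head_density.parameters()
        for h in self.head_levels:
            ps += h.parameters()
        return ps

    def density_head_parameters(self) -> list[Param]:
        return self.head_density.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def layer_census(self) -> dict[str, int]:
        """Topology fingerprint, independent of width_scale."""
        kinds: dict[str, int] = {}
        for l in self.trunk.layers:
            kinds[type(l).__name__] = kinds.get(type(l).__name__, 0) + 1
        kinds["DilatedConv"] = sum(
            1 for l in self.trunk.layers if isinstance(l, Conv2d) and l.dilation > 1
        )
        kinds["LevelHeads"] = len(self.head_levels)
        return kinds

    # ----------------------------------------------------------------- forward
    @staticmethod
    def _normalize(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
        img = img.astype(np.float64)
        if img.max() > 1.0:
            img = img / 255.0
        return img.transpose(2, 0, 1)

    def forward(self, image: np.ndarray) -> PredictorOutputs:
        x = self._normalize(image)
        _, h, w = x.shape
        f = self.cfg.downsample_factor
        pad_h, pad_w = (-h) % f, (-w) % f
        if pad_h or pad_w:
            x = np.pad(x, ((0, 0), (0, pad_h), (0, pad_w)))
        out_h, out_w = -(-h // f), -(-w // f)
        feat = self.trunk.forward(x)
        density = self.head_density.forward(feat)[0]
        logits = [hd.forward(feat) for hd in self.head_levels]
        probs = np.stack(
            [sg.forward(lg)[0] for sg, lg in zip(self._level_sigmoids, logits)]
        )
        self._cache = {"feat_shape": feat.shape, "out_hw": (out_h, out_w)}
        return PredictorOutputs(
            density=DensityMap(density[:out_h, :out_w], resolution_divisor=f),
            level_probs=probs[:, :out_h, :out_w],
        )

    def backward(self, g_density: np.ndarray | None, g_level_probs: np.ndarray | None) -> None:
        """Accumulate parameter gradients for the last ``forward``.

        ``g_density`` is dL/d(density map), ``g_level_probs`` is
        dL/d(level probabilities), either may be None (that head untouched).
        Gradients over any right/bottom padding are zero by construction.
        """
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        fc, fh, fw = self._cache["feat_shape"]
        out_h, out_w = self._cache["out_hw"]
        g_feat = np.zeros((fc, fh, fw))
        if g_density is not None:
            g = np.zeros((1, fh, fw))
            g[0, :out_h, :out_w] = g_density
            g_feat += self.head_density.backward(g)
        if g_level_probs is not None:
            for i, (sg, hd) in enumerate(zip(self._level_sigmoids, self.head_levels)):
                g = np.zeros((1, fh, fw))
                g[0, :out_h, :out_w] = g_level_probs[i]
                g_feat += hd.backward(sg.backward(g))
        self.trunk.backward(g_feat)

    # -------------------------------------------------------------- state dict
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.value for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            a = np.asarray(arrays[f"param_{i}"])
            if a.shape != p.value.shape:
                raise ValueError(f"checkpoint parameter {i} has shape {a.shape}, "
                                 f"model expects {p.value.shape}")
            p.value = a.astype(np.float64)


def build_network(cfg: NetworkConfig, seed: int = 0) -> CDMENet:
    """Construct a seed-reproducible counting network."""
    return CDMENet(cfg, seed=seed)


def save_checkpoint(path: str | Path, model: CDMENet,
                    thresholds: ThresholdSet | None = None) -> None:
    """Serialise parameters + config (+ frozen thresholds) to a single file."""
    meta = {
        "format": CHECKPOINT_FORMAT,
        "config": asdict(model.cfg),
        "seed": model.seed,
        "thresholds": None
        if thresholds is None
        else {
            "quantile_positions": list(thresholds.quantile_positions),
            "thresholds": list(thresholds.thresholds),
        },
    }
    with open(path, "wb") as fh:  # file handle: keep the exact path, any suffix
        np.savez_compressed(
            fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **model.state_arrays(),
        )


def load_checkpoint(path: str | Path) -> tuple[CDMENet, ThresholdSet | None]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognised checkpoint format: {meta.get('format')}")
        cfg_d = meta["config"]
        cfg_d["channel_plan"] = tuple(cfg_d["channel_plan"])
        cfg = NetworkConfig(**cfg_d)
        model = CDMENet(cfg, seed=meta.get("seed", 0))
        model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    th = None
    if meta["thresholds"] is not None:
        th = ThresholdSet(
            tuple(meta["thresholds"]["quantile_positions"]),
            tuple(meta["thresholds"]["thresholds"]),
        )
    return model, th
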