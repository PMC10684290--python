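"""Counting metrics (MAE, RMSE, R²) and comparison-table arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DensityMap

__all__ = [
    "EvalMetrics",
    "MethodRow",
    "count_from_density",
    "compute_metrics",
    "relative_improvement",
    "load_comparison_table",
    "published_benchmark",
]


@dataclass
class EvalMetrics:
    """Per-image-count error summary; ``r2`` is None when undefined."""

    mae: float
    rmse: float
    r2: float | None
    n_images: int


@dataclass
class MethodRow:
    """One comparison-table row; missing metrics are None."""

    method: str
    mae: float | None = None
    rmse: float | None = None
    r2: float | None = None

    @property
    def missing(self) -> bool:
        return self.mae is None or self.rmse is None or self.r2 is None


def count_from_density(d: DensityMap, clip_negative: bool = False) -> float:
    """Predicted object count: the integral (pixel sum) of the density map.

    Sum-preserving downsampling makes this resolution independent.  Raw
    regression maps may dip below zero; ``clip_negative`` floors pixels at 0
    before summing for sensitivity analysis (off by default).
    """
    v = d.values
    if clip_negative:
        v = np.maximum(v, 0.0)
    return float(v.sum())


def compute_metrics(truths, predictions) -> EvalMetrics:
    """MAE, RMSE and coefficient of determination over per-image counts.

    R² = 1 - Σ(C-C')² / Σ(C-C̄)²; undefined (None) when all true counts are
    identical.
    """
    c = np.asarray(truths, dtype=np.float64)
    cp = np.asarray(predictions, dtype=np.float64)
    if c.shape != cp.shape or c.ndim != 1 or len(c) == 0:
        raise ValueError("truths and predictions must be equal-length nonempty vectors")
    err = c - cp
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    ss_tot = float(((c - c.mean()) ** 2).sum())
    r2 = None if ss_tot == 0 else 1.0 - float((err**2).sum()) / ss_tot
    return EvalMetrics(mae=mae, rmse=rmse, r2=r2, n_images=len(c))


def relative_improvement(
    ours: MethodRow, competitors: list[MethodRow]
) -> tuple[float, float, float]:
    """(R² gain %, MAE reduction %, RMSE reduction %) vs the best competitor.

    The baseline is chosen per metric independently — lowest competitor MAE,
    lowest RMSE, highest R² — which makes each improvement the conservative
    ("at least") figure.  Competitors with a missing metric are skipped for
    that metric.
    """
    maes = [c.mae for c in competitors if c.mae is not None]
    rmses = [c.rmse for c in competitors if c.rmse is not None]
    r2s = [c.r2 for c in competitors if c.r2 is not None]
    if not (maes and rmses and r2s):
        raise ValueError("no competitor supplies a complete set of metrics")
    best_mae, best_rmse, best_r2 = min(maes), min(rmses), max(r2s)
    r2_gain = 100.0 * (ours.r2 - best_r2) / best_r2
    mae_red = 100.0 * (best_mae - ours.mae) / best_mae
    rmse_red = 100.0 * (best_rmse - ours.rmse) / best_rmse
    return (r2_gain, mae_red, rmse_red)


def load_comparison_table(path: str | Path) -> pd.DataFrame:
    """Read a method-comparison CSV (columns method,ratio,mae,rmse,r2).

    Empty cells mark metrics a method did not report.
    """
    df = pd.read_csv(path)
    required = {"method", "ratio", "mae", "rmse", "r2"}
    if not required.issubset(df.columns):
        raise ValueError(f"comparison table needs columns {sorted(required)}")
    return df


def published_benchmark() -> pd.DataFrame:
    """Published field grape-berry benchmark results shipped with the package."""
    with resources.as_file(
        resources.files("cdmenet.data") / "field_grape_benchmark.csv"
    ) as p:
        return load_comparison_table(p)


def rows_for_ratio(df: pd.DataFrame, ratio: float) -> tuple[MethodRow, list[MethodRow]]:
    """Split a benchmark table at one labeled ratio into (ours, competitors)."""
    sub = df[np.isclose(df["ratio"], ratio)]
    if sub.empty:
        raise ValueError(f"no benchmark rows at ratio {ratio}")
    ours = None
    comps = []
    for _, r in sub.iterrows():
        row = MethodRow(
            method=r["method"],
            mae=None if math.isnan(r["mae"]) else float(r["mae"]),
            rmse=None if math.isnan(r["rmse"]) else float(r["rmse"]),
            r2=None if math.isnan(r["r2"]) else float(r["r2"]),
        )
        if r["method"].lower().startswith("cdmenet"):
            ours = row
        else:
            comps.append(row)
    if ours is None:
        raise ValueError("benchmark table lacks a CDMENet row at this ratio")
    return ours, comps
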