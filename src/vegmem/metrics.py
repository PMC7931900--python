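"""Skill metrics at pixel, biome and global level, and the memory statistic.

Two R-squared variants are provided: ``corr2`` (squared Pearson correlation,
the default — it stays in [0, 1] even for anti-correlated predictions) and
``nse`` (Nash-Sutcliffe efficiency, 1 - SSE/SST, shift- and scale-sensitive,
used for pooled headline numbers).  Biome metrics are computed on pixel-area
weighted biome-mean series and aggregated globally with biome-area weights:

    R2_global = (1/A) * sum_b R2_b * A_b      (likewise RMSE)

The memory effect of model M_n is Mem_n = R2_n - R2_0, the gain in explained
variance from allowing n steps of ordered temporal context; the headline
Mem uses M_full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BiomeMap, SpatioTemporalCube

__all__ = [
    "r_squared", "rmse", "biome_metrics", "global_metric", "mem",
    "pooled_metrics", "pixel_r_squared", "MemoryResult",
]


def _paired(obs: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, float).ravel()
    pred = np.asarray(pred, float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    ok = np.isfinite(obs) & np.isfinite(pred)
    return obs[ok], pred[ok]


def r_squared(obs: np.ndarray, pred: np.ndarray, variant: str = "corr2") -> float:
    """R-squared of predictions against observations on valid pairs.

    Returns NaN (flagged undefined) when fewer than 3 pairs remain or the
    observations have zero variance.
    """
    o, p = _paired(obs, pred)
    if o.size < 3:
        return float("nan")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        return float("nan")
    if variant == "corr2":
        sp = float(np.sum((p - p.mean()) ** 2))
        if sp == 0.0:
            return float("nan")
        r = float(np.sum((o - o.mean()) * (p - p.mean()))) / np.sqrt(sst * sp)
        return r * r
    if variant == "nse":
        sse = float(np.sum((o - p) ** 2))
        return 1.0 - sse / sst
    raise ValueError(f"unknown R^2 variant {variant!r}")


def rmse(obs: np.ndarray, pred: np.ndarray) -> float:
    """Root mean squared error over valid pairs (NaN when no pairs)."""
    o, p = _paired(obs, pred)
    if o.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def pixel_r_squared(obs: np.ndarray, pred: np.ndarray,
                    variant: str = "corr2") -> np.ndarray:
    """Vectorized per-row R^2 for (pixel, time) arrays with NaN as missing."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    ok = np.isfinite(obs) & np.isfinite(pred)
    n = ok.sum(axis=1)
    o = np.where(ok, obs, 0.0)
    p = np.where(ok, pred, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        om = o.sum(axis=1) / n
        pm = p.sum(axis=1) / n
        oc = np.where(ok, obs - om[:, None], 0.0)
        pc = np.where(ok, pred - pm[:, None], 0.0)
        sso = np.sum(oc * oc, axis=1)
        ssp = np.sum(pc * pc, axis=1)
        sop = np.sum(oc * pc, axis=1)
        if variant == "corr2":
            out = (sop * sop) / (sso * ssp)
        elif variant == "nse":
            res = np.where(ok, obs - pred, 0.0)
            out = 1.0 - np.sum(res * res, axis=1) / sso
        else:
            raise ValueError(f"unknown R^2 variant {variant!r}")
    out = np.where((n >= 3) & (sso > 0), out, np.nan)
    return out


def _weighted_series(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Area-weighted mean over pixels per step, NaN-aware."""
    ok = np.isfinite(values)
    w = np.where(ok, weights[:, None], 0.0)
    num = np.nansum(np.where(ok, values, 0.0) * w, axis=0)
    den = w.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def biome_metrics(obs: SpatioTemporalCube | np.ndarray,
                  pred: SpatioTemporalCube | np.ndarray,
                  biomes: BiomeMap,
                  weights: np.ndarray | None = None,
                  variant: str = "corr2",
                  remove_mean: bool = False) -> pd.DataFrame:
    """Per-biome R^2 and RMSE on area-weighted biome-mean series.

    Observed and predicted series are each aggregated to a biome-mean series
    with cos-latitude pixel weights, then scored.  ``remove_mean`` subtracts
    each pixel's own time mean first (removes purely spatial variability).
    Empty biomes are skipped with a warning row omitted.
    """
    o = obs.masked() if isinstance(obs, SpatioTemporalCube) else np.asarray(obs, float)
    p = pred.masked() if isinstance(pred, SpatioTemporalCube) else np.asarray(pred, float)
    if weights is None:
        if isinstance(obs, SpatioTemporalCube):
            weights = obs.area_weights()
        else:
            weights = np.ones(o.shape[0])
    if remove_mean:
        o = o - np.nanmean(o, axis=1, keepdims=True)
        p = p - np.nanmean(p, axis=1, keepdims=True)
    rows = []
    for b in biomes.biomes:
        idx = biomes.pixels_of(b)
        if idx.size == 0:
            continue
        so = _weighted_series(o[idx], weights[idx])
        sp = _weighted_series(p[idx], weights[idx])
        rows.append({
            "biome": b,
            "area": biomes.biome_area[b],
            "n_pixels": int(idx.size),
            "r2": r_squared(so, sp, variant=variant),
            "rmse": rmse(so, sp),
        })
    return pd.DataFrame(rows)


def global_metric(values: np.ndarray, areas: np.ndarray) -> float:
    """Biome-area weighted mean of per-biome metric values."""
    values = np.asarray(values, float)
    areas = np.asarray(areas, float)
    ok = np.isfinite(values)
    a = float(areas[ok].sum())
    if a <= 0:
        raise ValueError("total biome area must be positive")
    return float(np.sum(values[ok] * areas[ok]) / a)


def pooled_metrics(obs: np.ndarray, pred: np.ndarray,
                   variant: str = "nse") -> dict[str, float]:
    """Pooled (all pixels and steps combined) R^2 and RMSE."""
    return {"r2": r_squared(obs, pred, variant=variant), "rmse": rmse(obs, pred)}


@dataclass
class MemoryResult:
    """Mem_n = R2_n - R2_0: the memory effect of model M_n over M_0."""

    value: float | np.ndarray
    model_n: str
    model_0: str

    def __float__(self) -> float:
        return float(self.value)


def mem(r2_n, r2_0, model_n: str = "M_full", model_0: str = "M_0"
        ) -> MemoryResult:
    """Difference in explained variance between two models (may be < 0)."""
    a = np.asarray(r2_n, float)
    b = np.asarray(r2_0, float)
    if a.shape != b.shape:
        raise ValueError("Mem requires both R^2 on the same domain")
    diff = a - b
    return MemoryResult(value=float(diff) if diff.ndim == 0 else diff,
                        model_n=model_n, model_0=model_0)
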