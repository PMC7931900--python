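"""Summary products: memory-length curves, climate-space bins, monthly memory.

These condense the per-model metric maps into the study's standard views:
how the memory effect grows (and saturates) with the permitted memory length
per biome; how it distributes across the climate space of mean annual
temperature and precipitation; in which calendar months the full-memory
model outperforms the no-memory model; and a regional error-series example.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BiomeMap, SpatioTemporalCube
from .metrics import pixel_r_squared, r_squared
from .permute import FULL, memory_days, model_label
from .preprocess import decompose

__all__ = ["memory_curve", "ClimateSpaceGrid", "climate_space",
           "monthly_memory", "regional_example"]


def _model_key(n) -> str:
    return model_label(n)


def memory_curve(pixel_r2: dict, biomes: BiomeMap) -> pd.DataFrame:
    """Per-biome and global memory-effect curves over the model family.

    ``pixel_r2`` maps each memory bound n (int or FULL) to a per-pixel R^2
    array.  Mem_n is computed pixelwise against the n = 0 baseline; rows
    report the across-pixel mean and interquartile range per biome and
    globally, annotated with the memory length in days (15 per step).
    """
    if not any(k == 0 for k in pixel_r2 if k is not FULL):
        raise ValueError("memory curve needs the M_0 baseline")
    base = pixel_r2[0]
    rows = []
    scopes = [("global", np.flatnonzero(biomes.retained))]
    scopes += [(b, biomes.pixels_of(b)) for b in biomes.biomes]
    full_r2 = pixel_r2.get(FULL)
    for n, r2n in pixel_r2.items():
        memn = np.asarray(r2n, float) - np.asarray(base, float)
        for scope, idx in scopes:
            vals = memn[idx]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            row = {
                "scope": scope, "model": _model_key(n), "n": n,
                "days": memory_days(n),
                "mem_mean": float(vals.mean()),
                "mem_q1": float(np.quantile(vals, 0.25)),
                "mem_q3": float(np.quantile(vals, 0.75)),
            }
            if full_r2 is not None:
                fv = np.asarray(full_r2, float)[idx]
                fv = fv[np.isfinite(fv)]
                row["r2_full"] = float(fv.mean()) if fv.size else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClimateSpaceGrid:
    """Mean memory effect binned over annual precipitation x temperature."""

    temp_edges: np.ndarray
    precip_edges: np.ndarray
    mean_mem: np.ndarray   # (n_temp_bins, n_precip_bins)
    count: np.ndarray
    masked: np.ndarray     # True where count < min_count
    min_count: int


def climate_space(mem_map: np.ndarray, mean_temp: np.ndarray,
                  mean_precip: np.ndarray,
                  temp_edges: np.ndarray, precip_edges: np.ndarray,
                  min_count: int = 10) -> ClimateSpaceGrid:
    """Bin per-pixel memory effects in the climate space.

    Cells with fewer than ``min_count`` member pixels are masked (reported
    but flagged), mirroring how sparsely populated climate bins are greyed
    out.  Pixels with non-finite Mem or climate coordinates are ignored.
    """
    temp_edges = np.asarray(temp_edges, float)
    precip_edges = np.asarray(precip_edges, float)
    for e, nm in ((temp_edges, "temperature"), (precip_edges, "precipitation")):
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError(f"{nm} bin edges must be strictly increasing")
    mem_map = np.asarray(mem_map, float)
    ok = (np.isfinite(mem_map) & np.isfinite(mean_temp)
          & np.isfinite(mean_precip))
    ti = np.digitize(np.asarray(mean_temp, float)[ok], temp_edges) - 1
    pi = np.digitize(np.asarray(mean_precip, float)[ok], precip_edges) - 1
    nt, npb = temp_edges.size - 1, precip_edges.size - 1
    inside = (ti >= 0) & (ti < nt) & (pi >= 0) & (pi < npb)
    ti, pi, vals = ti[inside], pi[inside], mem_map[ok][inside]
    count = np.zeros((nt, npb), int)
    total = np.zeros((nt, npb))
    np.add.at(count, (ti, pi), 1)
    np.add.at(total, (ti, pi), vals)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ClimateSpaceGrid(
        temp_edges=temp_edges, precip_edges=precip_edges, mean_mem=mean,
        count=count, masked=count < min_count, min_count=min_count,
    )


def _weighted_series(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    ok = np.isfinite(values)
    w = np.where(ok, weights[:, None], 0.0)
    num = np.sum(np.where(ok, values, 0.0) * w, axis=0)
    den = w.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def monthly_memory(obs: SpatioTemporalCube, pred_full: np.ndarray,
                   pred_0: np.ndarray, biomes: BiomeMap,
                   min_pixels: int = 10, variant: str = "corr2"
                   ) -> pd.DataFrame:
    """Across-year explained-variance gain of M_full over M_0 per month.

    For each biome and hemisphere the pixel series are area-averaged; for
    each calendar month, the month's steps are pooled across years and the
    across-year R^2 of each model's series against the observations is
    computed on that pool; the reported value is the difference.  Biome x
    hemisphere cells with fewer than ``min_pixels`` pixels are suppressed.
    """
    if obs.time.n_years < 2:
        raise ValueError("monthly memory needs at least 2 years of data")
    months = obs.time.months()
    w = obs.area_weights()
    o = obs.masked()
    rows = []
    for b in biomes.biomes:
        for hemi, sel in (("N", obs.lat >= 0), ("S", obs.lat < 0)):
            idx = biomes.pixels_of(b)
            idx = idx[sel[idx]]
            if idx.size < min_pixels:
                continue
            so = _weighted_series(o[idx], w[idx])
            sf = _weighted_series(np.asarray(pred_full, float)[idx], w[idx])
            sz = _weighted_series(np.asarray(pred_0, float)[idx], w[idx])
            for m in range(1, 13):
                steps = months == m
                r2f = r_squared(so[steps], sf[steps], variant=variant)
                r2z = r_squared(so[steps], sz[steps], variant=variant)
                rows.append({
                    "biome": b, "hemisphere": hemi, "month": m,
                    "n_pixels": int(idx.size),
                    "r2_full": r2f, "r2_0": r2z, "mem": r2f - r2z,
                })
    return pd.DataFrame(rows)


def regional_example(obs: SpatioTemporalCube, preds: dict[str, np.ndarray],
                     bbox: tuple[float, float, float, float]) -> pd.DataFrame:
    """Regional time series of absolute error and observed components.

    ``bbox`` is (lat_min, lat_max, lon_min, lon_max).  For every model the
    mean and population standard deviation over region pixels of the
    absolute error at each step are reported, together with the region-mean
    observed RAW/MSC (tiled)/ANO series.
    """
    lat_min, lat_max, lon_min, lon_max = bbox
    sel = ((obs.lat >= lat_min) & (obs.lat <= lat_max)
           & (obs.lon >= lon_min) & (obs.lon <= lon_max))
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError("empty region")
    o = obs.masked()
    dec = decompose(obs)
    out = {"step": np.arange(obs.n_steps),
           "obs_raw": np.nanmean(o[idx], axis=0),
           "obs_msc": np.nanmean(dec.msc_tiled()[idx], axis=0),
           "obs_ano": np.nanmean(dec.ano.masked()[idx], axis=0)}
    for label, pred in preds.items():
        err = np.abs(np.asarray(pred, float)[idx] - o[idx])
        out[f"abs_err_mean_{label}"] = np.nanmean(err, axis=0)
        out[f"abs_err_std_{label}"] = np.nanstd(err, axis=0)  # population std
    return pd.DataFrame(out)
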