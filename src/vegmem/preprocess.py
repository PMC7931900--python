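"""Quality filtering, spatial aggregation, decomposition and standardization.

Filtering rules follow the "more than" convention: a pixel-time-step survives
aggregation when *at most* half of its contributing fine cells are missing,
and a pixel survives the time-coverage / land-cover screens when its missing
(or water, or barren) fraction does not *exceed* the threshold — boundaries
are strict inequalities on the "drop" side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import SpatioTemporalCube, StaticFieldSet, TimeAxis

log = logging.getLogger(__name__)

__all__ = [
    "Decomposition",
    "aggregate_target",
    "filter_pixels",
    "decompose",
    "Standardizer",
    "standardize",
]


@dataclass
class Decomposition:
    """RAW series, median seasonal cycle (MSC) and anomalies (ANO).

    ``msc`` spans a single year (``steps_per_year`` steps); ``ano`` is the raw
    series minus the MSC tiled over all years, so ``raw = msc_tiled + ano``
    wherever all three are valid.
    """

    raw: SpatioTemporalCube
    msc: SpatioTemporalCube
    ano: SpatioTemporalCube

    def component(self, which: str) -> SpatioTemporalCube:
        which = which.upper()
        if which not in ("RAW", "MSC", "ANO"):
            raise ValueError(f"unknown decomposition component {which!r}")
        return {"RAW": self.raw, "MSC": self.msc, "ANO": self.ano}[which]

    def msc_tiled(self) -> np.ndarray:
        """MSC repeated over the raw time span (NaN where invalid)."""
        reps = self.raw.time.n_years
        return np.tile(self.msc.masked(), (1, reps))


def aggregate_target(fine: SpatioTemporalCube, factor: int,
                     max_missing: float = 0.5) -> SpatioTemporalCube:
    """Block-average a fine grid to a coarser one.

    Each coarse pixel-time-step is the mean of the valid fine values in its
    ``factor x factor`` block; it is dropped when more than ``max_missing`` of
    the block is missing.  Edge rows/columns not divisible by ``factor`` are
    trimmed (and logged).
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    if fine.grid_shape is None:
        raise ValueError("aggregation needs a 2-D grid layout")
    h, w = fine.grid_shape
    hh, ww = (h // factor) * factor, (w // factor) * factor
    if (hh, ww) != (h, w):
        log.info("aggregate_target: trimming grid %dx%d -> %dx%d", h, w, hh, ww)
    t = fine.n_steps
    vals = np.where(fine.valid, fine.values, 0.0).reshape(h, w, t)[:hh, :ww]
    ok = fine.valid.reshape(h, w, t)[:hh, :ww]
    lat = fine.lat.reshape(h, w)[:hh, :ww]
    lon = fine.lon.reshape(h, w)[:hh, :ww]

    def blocks(a, reduce):  # (hh, ww, ...) -> (hc, wc, ...)
        s = a.reshape(hh // factor, factor, ww // factor, factor, *a.shape[2:])
        return reduce(s, axis=(1, 3))

    n_valid = blocks(ok.astype(float), np.sum)
    total = float(factor * factor)
    coarse_ok = 1.0 - n_valid / total <= max_missing  # "more than" missing drops
    with np.errstate(invalid="ignore"):
        mean = np.where(n_valid > 0, blocks(vals, np.sum) / np.maximum(n_valid, 1), 0.0)
    mean = np.where(coarse_ok, mean, 0.0)
    clat = blocks(lat[..., None], np.mean)[..., 0]
    clon = blocks(lon[..., None], np.mean)[..., 0]
    hc, wc = hh // factor, ww // factor
    return SpatioTemporalCube(
        values=mean.reshape(hc * wc, t),
        valid=coarse_ok.reshape(hc * wc, t),
        lat=clat.ravel(),
        lon=clon.ravel(),
        time=fine.time,
        grid_shape=(hc, wc),
        name=fine.name,
    )


def filter_pixels(cube: SpatioTemporalCube, lcf: StaticFieldSet,
                  max_time_missing: float = 0.5, max_water: float = 0.2,
                  max_barren: float = 0.5,
                  water_field: str = "water_frac",
                  barren_field: str = "barren_frac") -> np.ndarray:
    """Pixel retention mask.

    A pixel is dropped when more than ``max_time_missing`` of its time series
    is missing, when its water land-cover fraction exceeds ``max_water``, or
    when its barren fraction exceeds ``max_barren``.
    """
    water = lcf[water_field]
    barren = lcf[barren_field]
    if water.shape[0] != cube.n_pixels:
        raise ValueError("land-cover fields do not align with cube pixels")
    missing_frac = 1.0 - cube.valid.mean(axis=1)
    keep = (
        (missing_frac <= max_time_missing)
        & (water <= max_water)
        & (barren <= max_barren)
    )
    log.info(
        "filter_pixels: retained %d/%d (time-missing dropped %d, water %d, barren %d)",
        int(keep.sum()), cube.n_pixels,
        int((missing_frac > max_time_missing).sum()),
        int((water > max_water).sum()), int((barren > max_barren).sum()),
    )
    return keep


def decompose(cube: SpatioTemporalCube, steps_per_year: int | None = None
              ) -> Decomposition:
    """Split a cube into median seasonal cycle and anomalies.

    The MSC at step-of-year ``s`` is the median over years of the valid values
    at that step; the anomaly is the raw value minus the (tiled) MSC.  Where
    no year contributes a valid value, both MSC and ANO are invalid.
    """
    spy = steps_per_year or cube.time.steps_per_year
    if cube.n_steps % spy:
        raise ValueError("cube must span an integer number of years")
    years = cube.n_steps // spy
    data = cube.masked().reshape(cube.n_pixels, years, spy)
    with np.errstate(all="ignore"):
        msc_vals = np.nanmedian(data, axis=1)  # (P, spy)
    msc_axis = TimeAxis(cube.time.start_year, spy, spy)
    msc = SpatioTemporalCube.from_masked(
        msc_vals, cube.lat, cube.lon, msc_axis, cube.grid_shape,
        name=f"{cube.name}_msc",
    )
    tiled = np.tile(msc_vals, (1, years))
    ano = SpatioTemporalCube.from_masked(
        cube.masked() - tiled, cube.lat, cube.lon, cube.time, cube.grid_shape,
        name=f"{cube.name}_ano",
    )
    return Decomposition(raw=cube, msc=msc, ano=ano)


class Standardizer:
    """Per-variable affine transform fitted on a reference selection.

    Means and scales are estimated on training data only and reused unchanged
    at validation/prediction time.
    """

    def __init__(self, means: dict[str, float], scales: dict[str, float]):
        self.means = means
        self.scales = scales

    def transform(self, name: str, x: np.ndarray) -> np.ndarray:
        return (x - self.means[name]) / self.scales[name]

    def inverse(self, name: str, z: np.ndarray) -> np.ndarray:
        return z * self.scales[name] + self.means[name]


def standardize(arrays: dict[str, np.ndarray],
                reference: dict[str, np.ndarray] | None = None
                ) -> tuple[dict[str, np.ndarray], Standardizer]:
    """Standardize each named array to zero mean / unit variance.

    ``reference`` optionally supplies, per variable, a boolean selection of
    the entries used to estimate the statistics (e.g. training pixels and
    steps); the fitted transform is then applied to the full array.
    """
    means, scales, out = {}, {}, {}
    for name, arr in arrays.items():
        arr = np.asarray(arr, dtype=float)
        sel = np.ones(arr.shape, bool) if reference is None else reference[name]
        ref = arr[sel]
        ref = ref[np.isfinite(ref)]
        if ref.size == 0:
            raise ValueError(f"empty reference selection for {name!r}")
        m = float(ref.mean())
        s = float(ref.std())
        if s == 0.0:
            raise ValueError(f"zero-variance variable {name!r}")
        means[name], scales[name] = m, s
        out[name] = (arr - m) / s
    return out, Standardizer(means, scales)
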