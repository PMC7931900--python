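"""Gridded spatio-temporal data model and NetCDF I/O.

The package works on a flat pixel axis: cubes hold a ``(pixel, time)`` value
array plus a validity mask, per-pixel latitude/longitude, and a regular
15-daily time axis realized as a fixed number of steps per year (default 24,
i.e. exactly two steps per month).  Files on a ``(lat, lon, time)`` grid are
flattened on read; the original 2-D layout is retained as ``grid_shape`` so
that spatial cross-validation blocking can recover row/column coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "TimeAxis",
    "SpatioTemporalCube",
    "StaticFieldSet",
    "BiomeMap",
    "pixel_area",
    "steps_in_range",
    "read_cube",
    "write_cube",
]


def _netcdf_engine() -> str:
    """Pick an available xarray NetCDF backend."""
    try:
        import h5netcdf  # noqa: F401

        return "h5netcdf"
    except ImportError:  # pragma: no cover
        return "scipy"


@dataclass(frozen=True)
class TimeAxis:
    """Regular sub-monthly calendar: ``steps_per_year`` equal steps per year.

    Step ``i`` belongs to year ``start_year + i // steps_per_year`` and to
    step-of-year ``i % steps_per_year``.  With the default 24 steps per year
    each calendar month holds exactly two consecutive steps.
    """

    start_year: int
    n_steps: int
    steps_per_year: int = 24

    def __post_init__(self) -> None:
        if self.n_steps <= 0 or self.steps_per_year <= 0:
            raise ValueError("n_steps and steps_per_year must be positive")

    @property
    def n_years(self) -> int:
        if self.n_steps % self.steps_per_year:
            raise ValueError(
                f"time axis of {self.n_steps} steps does not span whole years "
                f"at {self.steps_per_year} steps/year"
            )
        return self.n_steps // self.steps_per_year

    @property
    def end_year(self) -> int:
        return self.start_year + (self.n_steps - 1) // self.steps_per_year

    def years(self) -> np.ndarray:
        """Calendar year of every step."""
        return self.start_year + np.arange(self.n_steps) // self.steps_per_year

    def steps_of_year(self) -> np.ndarray:
        """Step-of-year (0-based) of every step."""
        return np.arange(self.n_steps) % self.steps_per_year

    def months(self) -> np.ndarray:
        """Calendar month (1-12) of every step; 2 steps per month at 24/yr."""
        per_month = self.steps_per_year / 12.0
        return (self.steps_of_year() / per_month).astype(int) + 1

    def year_slice(self, year_start: int, year_stop: int) -> slice:
        """Half-open step range covering calendar years [year_start, year_stop)."""
        a = (year_start - self.start_year) * self.steps_per_year
        b = (year_stop - self.start_year) * self.steps_per_year
        if a < 0 or b > self.n_steps or a >= b:
            raise ValueError(f"years [{year_start}, {year_stop}) outside axis")
        return slice(a, b)


def steps_in_range(start_year: int, end_year: int, steps_per_year: int = 24) -> int:
    """Number of steps covering the inclusive year range."""
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    return (end_year - start_year + 1) * steps_per_year


def pixel_area(lat: np.ndarray | float) -> np.ndarray | float:
    """Relative pixel-area weight, proportional to cos(latitude).

    Standard approximation for equal-angle grids: cell area shrinks with the
    cosine of the latitude of the cell center.
    """
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    w = np.cos(np.deg2rad(lat))
    return float(w) if w.ndim == 0 else w


@dataclass
class SpatioTemporalCube:
    """A ``(pixel, time)`` real-valued grid with missing-value mask."""

    values: np.ndarray
    valid: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    time: TimeAxis
    grid_shape: tuple[int, int] | None = None
    name: str = "var"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share one shape")
        if self.values.ndim != 2:
            raise ValueError("values must be (pixel, time)")
        p, t = self.values.shape
        if t != self.time.n_steps:
            raise ValueError(
                f"values have {t} steps but time axis has {self.time.n_steps}"
            )
        if self.lat.shape != (p,) or self.lon.shape != (p,):
            raise ValueError("lat/lon must be per-pixel vectors")
        if self.grid_shape is not None:
            h, w = self.grid_shape
            if h * w != p:
                raise ValueError("grid_shape inconsistent with pixel count")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("non-finite values flagged as valid")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def masked(self) -> np.ndarray:
        """Values with invalid entries replaced by NaN."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def area_weights(self) -> np.ndarray:
        return pixel_area(self.lat)

    def copy_with(self, values: np.ndarray, valid: np.ndarray | None = None,
                  time: TimeAxis | None = None, name: str | None = None
                  ) -> "SpatioTemporalCube":
        return SpatioTemporalCube(
            values=values,
            valid=self.valid.copy() if valid is None else valid,
            lat=self.lat,
            lon=self.lon,
            time=self.time if time is None else time,
            grid_shape=self.grid_shape,
            name=self.name if name is None else name,
        )

    @classmethod
    def from_masked(cls, data: np.ndarray, lat, lon, time: TimeAxis,
                    grid_shape=None, name: str = "var") -> "SpatioTemporalCube":
        """Build from an array whose invalid entries are NaN."""
        data = np.asarray(data, dtype=float)
        valid = np.isfinite(data)
        vals = np.where(valid, data, 0.0)
        return cls(vals, valid, lat, lon, time, grid_shape, name)


class StaticFieldSet:
    """Per-pixel static predictor fields (soil properties, land-cover fractions).

    Fields whose name is listed in ``fraction_fields`` are validated to lie in
    [0, 1] wherever finite.
    """

    def __init__(self, fields: dict[str, np.ndarray],
                 fraction_fields: tuple[str, ...] = ()) -> None:
        if not fields:
            raise ValueError("empty field set")
        self.fields = {k: np.asarray(v, dtype=float) for k, v in fields.items()}
        n = {v.shape for v in self.fields.values()}
        if len(n) != 1 or next(iter(n)).__len__() != 1:
            raise ValueError("all static fields must be 1-D of equal length")
        self.fraction_fields = tuple(fraction_fields)
        for name in self.fraction_fields:
            f = self[name]
            ok = np.isfinite(f)
            if np.any((f[ok] < 0) | (f[ok] > 1)):
                raise ValueError(f"fraction field {name!r} outside [0, 1]")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.fields:
            raise KeyError(
                f"static field {name!r} not found; have {sorted(self.fields)}"
            )
        return self.fields[name]

    def __contains__(self, name: str) -> bool:
        return name in self.fields

    @property
    def names(self) -> list[str]:
        return list(self.fields)

    @property
    def n_pixels(self) -> int:
        return next(iter(self.fields.values())).shape[0]

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        """(pixel, field) matrix in the given (default: all) field order."""
        names = self.names if names is None else names
        return np.column_stack([self[n] for n in names])

    def subset(self, pixel_index: np.ndarray) -> "StaticFieldSet":
        return StaticFieldSet(
            {k: v[pixel_index] for k, v in self.fields.items()},
            self.fraction_fields,
        )


class BiomeMap:
    """Integer biome label per pixel with biome areas.

    Areas are computed from *retained* pixels only, using cos-latitude pixel
    weights; this choice is recorded in provenance sidecars on write.
    """

    def __init__(self, biome_id: np.ndarray, lat: np.ndarray,
                 retained: np.ndarray | None = None) -> None:
        self.biome_id = np.asarray(biome_id, dtype=int)
        lat = np.asarray(lat, dtype=float)
        if self.biome_id.shape != lat.shape:
            raise ValueError("biome_id and lat must align")
        if retained is None:
            retained = np.ones_like(self.biome_id, dtype=bool)
        self.retained = np.asarray(retained, dtype=bool)
        w = pixel_area(lat)
        self.biome_area: dict[int, float] = {}
        for b in np.unique(self.biome_id[self.retained]):
            sel = self.retained & (self.biome_id == b)
            self.biome_area[int(b)] = float(np.sum(w[sel]))
        self.total_area = float(sum(self.biome_area.values()))

    @property
    def biomes(self) -> list[int]:
        return sorted(self.biome_area)

    def pixels_of(self, biome: int) -> np.ndarray:
        return np.flatnonzero(self.retained & (self.biome_id == biome))

    def area_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"biome": self.biomes,
             "area": [self.biome_area[b] for b in self.biomes]}
        )


# ---------------------------------------------------------------------------
# NetCDF I/O

def write_cube(cube: SpatioTemporalCube, path: str | Path,
               variable: str | None = None,
               provenance: dict | None = None) -> Path:
    """Write a cube to NetCDF (CF-style flat pixel layout) plus a JSON sidecar."""
    path = Path(path)
    variable = variable or cube.name
    ds = xr.Dataset(
        {variable: (("pixel", "time"), cube.masked())},
        coords={
            "pixel": np.arange(cube.n_pixels),
            "time": np.arange(cube.n_steps),
            "lat": ("pixel", cube.lat),
            "lon": ("pixel", cube.lon),
        },
        attrs={
            "start_year": cube.time.start_year,
            "steps_per_year": cube.time.steps_per_year,
            "grid_height": -1 if cube.grid_shape is None else cube.grid_shape[0],
            "grid_width": -1 if cube.grid_shape is None else cube.grid_shape[1],
        },
    )
    ds.to_netcdf(path, engine=_netcdf_engine())
    sidecar = {
        "file": path.name,
        "variable": variable,
        "n_pixels": int(cube.n_pixels),
        "n_steps": int(cube.n_steps),
        "start_year": int(cube.time.start_year),
        "steps_per_year": int(cube.time.steps_per_year),
    }
    if provenance:
        sidecar.update(provenance)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )
    return path


def read_cube(path: str | Path, variable: str) -> SpatioTemporalCube:
    """Read a cube written by :func:`write_cube` or a (lat, lon, time) file.

    Fill values / NaNs become invalid entries.  The time coordinate must be a
    gap-free integer step index; offending steps are reported otherwise.
    """
    path = Path(path)
    with xr.open_dataset(path, engine=_netcdf_engine()) as ds:
        if variable not in ds:
            raise KeyError(
                f"variable {variable!r} not in {path.name}; "
                f"have {sorted(ds.data_vars)}"
            )
        da = ds[variable]
        attrs = dict(ds.attrs)
        if set(da.dims) >= {"lat", "lon", "time"}:
            da = da.transpose("lat", "lon", "time")
            lat2, lon2 = np.meshgrid(
                ds["lat"].values, ds["lon"].values, indexing="ij"
            )
            grid_shape = (lat2.shape[0], lat2.shape[1])
            data = da.values.reshape(-1, da.sizes["time"])
            lat, lon = lat2.ravel(), lon2.ravel()
        elif set(da.dims) == {"pixel", "time"}:
            da = da.transpose("pixel", "time")
            data = da.values
            lat = ds["lat"].values
            lon = ds["lon"].values
            h = int(attrs.get("grid_height", -1))
            w = int(attrs.get("grid_width", -1))
            grid_shape = (h, w) if h > 0 and w > 0 else None
        else:
            raise ValueError(
                f"variable {variable!r} must be (pixel, time) or "
                f"(lat, lon, time); has dims {da.dims}"
            )
        t = ds["time"].values
        dt = np.diff(t.astype(float))
        if t.size > 1 and not np.all(dt == dt[0]):
            bad = np.flatnonzero(dt != dt[0]).tolist()
            raise ValueError(f"irregular time axis at steps {bad}")
        axis = TimeAxis(
            start_year=int(attrs.get("start_year", 0)),
            n_steps=data.shape[1],
            steps_per_year=int(attrs.get("steps_per_year", 24)),
        )
    return SpatioTemporalCube.from_masked(
        np.asarray(data, dtype=float), lat, lon, axis, grid_shape, variable
    )


def write_static(statics: StaticFieldSet, lat, lon, path: str | Path) -> Path:
    path = Path(path)
    ds = xr.Dataset(
        {k: ("pixel", v) for k, v in statics.fields.items()},
        coords={"pixel": np.arange(statics.n_pixels),
                "lat": ("pixel", np.asarray(lat, float)),
                "lon": ("pixel", np.asarray(lon, float))},
        attrs={"fraction_fields": ",".join(statics.fraction_fields)},
    )
    ds.to_netcdf(path, engine=_netcdf_engine())
    return path


def read_static(path: str | Path) -> tuple[StaticFieldSet, np.ndarray, np.ndarray]:
    path = Path(path)
    with xr.open_dataset(path, engine=_netcdf_engine()) as ds:
        frac = tuple(x for x in ds.attrs.get("fraction_fields", "").split(",") if x)
        fields = {k: ds[k].values.astype(float) for k in ds.data_vars}
        lat = ds["lat"].values.astype(float)
        lon = ds["lon"].values.astype(float)
    return StaticFieldSet(fields, frac), lat, lon
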