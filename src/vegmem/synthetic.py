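"""Synthetic driver and vegetation cubes with a known, tunable memory length.

The generator emulates the structure of the real study inputs — seasonal
temperature/radiation with stochastic weather, pulsed precipitation, smooth
static soil/land-cover fields — on a small lat/lon grid spanning both
hemispheres (seasonal phase flips south of the equator).  The vegetation
proxy responds to a leaky soil-water store

    S_t = (1 - 1/tau) * S_{t-1} + P_t          (clipped to a capacity)

so the dependence of the target on antecedent precipitation decays
geometrically with rate ``1 - 1/tau``: ``tau`` sets the true memory length.
With ``tau = 1`` the store holds current precipitation only and the target is
memory-free.  The greenness response saturates Michaelis-style,
``V = V_max * S / (S + K)``, times a smooth temperature limitation, plus
observation noise, clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import SpatioTemporalCube, StaticFieldSet, TimeAxis

__all__ = [
    "SyntheticConfig",
    "gen_drivers",
    "gen_vegetation",
    "true_memory_length",
    "DYNAMIC_VARS",
]

DYNAMIC_VARS = ("tmean", "tmin", "tmax", "rhum", "srad", "precip")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic world.

    Temperatures in degC, radiation in W m-2, precipitation in mm per 15-day
    step.  ``tau`` is the soil-store persistence in steps; ``corr_len`` the
    spatial correlation length (pixels) of the random parameter fields.
    """

    height: int = 12
    width: int = 12
    years: int = 8
    steps_per_year: int = 24
    lat_span: tuple[float, float] = (55.0, -55.0)
    lon_span: tuple[float, float] = (0.0, 30.0)
    tau: float = 4.0
    store_capacity: float = 120.0
    v_max: float = 0.95
    k_half: float = 25.0
    temp_half: float = 8.0
    temp_scale: float = 4.0
    noise_sd: float = 0.02
    temp_mean: float = 16.0
    temp_amp: float = 10.0
    temp_spread: float = 4.0
    srad_mean: float = 200.0
    srad_amp: float = 90.0
    precip_rate: float = 0.45
    precip_mag: float = 25.0
    ar1_rho: float = 0.5
    weather_sd: float = 1.5
    corr_len: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.height, self.width, self.years, self.steps_per_year) <= 0:
            raise ValueError("grid sizes must be positive")

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    @property
    def n_steps(self) -> int:
        return self.years * self.steps_per_year

    def time_axis(self, start_year: int = 2000) -> TimeAxis:
        return TimeAxis(start_year, self.n_steps, self.steps_per_year)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        lat = np.linspace(*self.lat_span, self.height)
        lon = np.linspace(*self.lon_span, self.width)
        lat2, lon2 = np.meshgrid(lat, lon, indexing="ij")
        return lat2.ravel(), lon2.ravel()


def _smooth_field(rng: np.random.Generator, cfg: SyntheticConfig,
                  lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Spatially correlated random field mapped to [lo, hi], flat (pixel,)."""
    z = rng.standard_normal((cfg.height, cfg.width))
    z = gaussian_filter(z, sigma=cfg.corr_len, mode="nearest")
    z = (z - z.min()) / max(z.max() - z.min(), 1e-12)
    return (lo + (hi - lo) * z).ravel()


def _ar1(rng: np.random.Generator, shape: tuple[int, int], rho: float,
         sd: float) -> np.ndarray:
    """AR(1) noise along the last (time) axis."""
    p, t = shape
    out = np.empty((p, t))
    innov_sd = sd * math.sqrt(max(1.0 - rho * rho, 1e-12))
    out[:, 0] = rng.normal(0.0, sd, size=p)
    eps = rng.normal(0.0, innov_sd, size=(p, t))
    for i in range(1, t):
        out[:, i] = rho * out[:, i - 1] + eps[:, i]
    return out


def gen_drivers(cfg: SyntheticConfig
                ) -> tuple[dict[str, SpatioTemporalCube], StaticFieldSet]:
    """Generate the six dynamic driver cubes and the static field set.

    Temperature and radiation follow a sinusoidal seasonal cycle (phase
    flipped across hemispheres) plus AR(1) weather noise; precipitation is a
    seasonally modulated pulse process, nonnegative by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    lat, lon = cfg.coords()
    axis = cfg.time_axis()
    p, t = cfg.n_pixels, cfg.n_steps
    phase = np.where(lat < 0, 0.5, 0.0)[:, None]  # hemisphere flip
    frac = (np.arange(t) % cfg.steps_per_year) / cfg.steps_per_year
    season = np.sin(2 * np.pi * (frac[None, :] - 0.25 - phase))  # peak mid-year N

    amp_t = cfg.temp_amp * (0.75 + 0.5 * _smooth_field(rng, cfg))[:, None]
    mean_t = cfg.temp_mean + 6.0 * (_smooth_field(rng, cfg) - 0.5)[:, None]
    tmean = mean_t + amp_t * season + _ar1(rng, (p, t), cfg.ar1_rho, cfg.weather_sd)
    spread = cfg.temp_spread * (0.8 + 0.4 * _smooth_field(rng, cfg))[:, None]
    tmin = tmean - spread + _ar1(rng, (p, t), cfg.ar1_rho, 0.5 * cfg.weather_sd)
    tmax = tmean + spread + _ar1(rng, (p, t), cfg.ar1_rho, 0.5 * cfg.weather_sd)

    srad = np.clip(
        cfg.srad_mean + cfg.srad_amp * season
        + _ar1(rng, (p, t), cfg.ar1_rho, 8.0 * cfg.weather_sd),
        0.0, None,
    )

    # wet season aligned with the warm season; pulse occurrence Bernoulli
    rate = np.clip(cfg.precip_rate * (1.0 + 0.8 * season), 0.0, 1.0)
    pulses = rng.random((p, t)) < rate
    mag = rng.exponential(cfg.precip_mag, size=(p, t))
    precip = np.where(pulses, mag, 0.0)

    rhum = np.clip(
        0.55 - 0.012 * (tmean - cfg.temp_mean) + 0.004 * precip
        + _ar1(rng, (p, t), cfg.ar1_rho, 0.04),
        0.0, 1.0,
    )

    def cube(vals, name):
        return SpatioTemporalCube(
            values=vals, valid=np.ones_like(vals, bool), lat=lat, lon=lon,
            time=axis, grid_shape=(cfg.height, cfg.width), name=name,
        )

    drivers = {
        "tmean": cube(tmean, "tmean"),
        "tmin": cube(tmin, "tmin"),
        "tmax": cube(tmax, "tmax"),
        "rhum": cube(rhum, "rhum"),
        "srad": cube(srad, "srad"),
        "precip": cube(precip, "precip"),
    }
    statics = StaticFieldSet(
        {
            "awc": _smooth_field(rng, cfg, 0.2, 1.0),
            "wtd": _smooth_field(rng, cfg, 0.0, 1.0),
            "water_frac": _smooth_field(rng, cfg, 0.0, 0.12),
            "barren_frac": _smooth_field(rng, cfg, 0.0, 0.3),
            "c4_frac": _smooth_field(rng, cfg, 0.0, 1.0),
        },
        fraction_fields=("water_frac", "barren_frac", "c4_frac"),
    )
    return drivers, statics


def gen_vegetation(drivers: dict[str, SpatioTemporalCube], cfg: SyntheticConfig
                   ) -> tuple[SpatioTemporalCube, np.ndarray]:
    """Vegetation-proxy cube driven by the leaky soil store, plus the store.

    The latent store is returned for diagnostics only; models never see it.
    """
    precip = drivers["precip"]
    tmean = drivers["tmean"]
    if precip.values.shape != tmean.values.shape:
        raise ValueError("driver cubes must share one grid and time axis")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    p, t = precip.values.shape
    decay = 1.0 - 1.0 / cfg.tau
    store = np.empty((p, t))
    s = np.zeros(p)
    for i in range(t):
        s = np.minimum(decay * s + precip.values[:, i], cfg.store_capacity)
        store[:, i] = s
    temp_limit = 1.0 / (1.0 + np.exp(-(tmean.values - cfg.temp_half) / cfg.temp_scale))
    v = cfg.v_max * store / (store + cfg.k_half) * temp_limit
    v = np.clip(v + rng.normal(0.0, cfg.noise_sd, size=(p, t)), 0.0, 1.0)
    veg = precip.copy_with(values=v, valid=np.ones_like(v, bool), name="ndvi")
    return veg, store


def true_memory_length(tau: float, threshold: float = 0.05) -> int:
    """Smallest k with residual store influence (1 - 1/tau)^k <= threshold.

    The ground-truth memory length of the generator: after k steps an
    antecedent precipitation pulse retains at most ``threshold`` of its
    original weight in the store.  ``tau = 1`` has no carry-over at all.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if threshold >= 1.0 or tau == 1:
        return 0
    decay = 1.0 - 1.0 / tau
    k = math.ceil(math.log(threshold) / math.log(decay))
    while decay ** (k - 1) <= threshold:  # guard float edge
        k -= 1
    return max(k, 0)
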