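"""Top-level modelling interface.

:class:`MemoryEffectModel` bundles a target cube, driver cubes and static
fields with a cross-validation design and a family of memory-bounded
sequence models; :meth:`MemoryEffectModel.fit` trains every model of the
family under the blocked cross-validation and returns a
:class:`MemoryEffectResults` carrying cross-validated predictions, skill
metrics per decomposition (RAW/MSC/ANO), memory-effect estimates and the
permutation significance test, with a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import crossval, nn, summaries
from .grid import BiomeMap, SpatioTemporalCube, StaticFieldSet
from .metrics import (biome_metrics, global_metric, mem, pixel_r_squared,
                      pooled_metrics)
from .permute import FULL, model_label
from .preprocess import decompose, filter_pixels
from .significance import SignificanceResult, max_stat_test
from .synthetic import SyntheticConfig, gen_drivers, gen_vegetation

log = logging.getLogger(__name__)

__all__ = ["MemoryEffectModel", "MemoryEffectResults"]

DECOMPS = ("RAW", "MSC", "ANO")


def _default_temporal(total_years: int) -> tuple[int, int, int]:
    """(k, fold_years, overlap) satisfying k*L - (k-1)*ov == total_years."""
    for k in (4, 3, 2):
        for ov in (1, 0):
            num = total_years + (k - 1) * ov
            if num % k == 0 and num // k > ov:
                return k, num // k, ov
    raise ValueError(f"no temporal fold plan for {total_years} years")


class MemoryEffectModel:
    """Memory-effect analysis of a vegetation proxy under climate drivers.

    Parameters
    ----------
    target : SpatioTemporalCube
        The (pixel, time) vegetation-state proxy (e.g. NDVI-like, in [0, 1]).
    drivers : dict of SpatioTemporalCube
        Dynamic predictor cubes on the same grid and time axis.
    statics : StaticFieldSet, optional
        Per-pixel static predictors (soil properties, land-cover fractions).
    biomes : BiomeMap, optional
        Aggregation regions for area-weighted metrics; a single global biome
        is assumed when omitted.
    memory_lengths : sequence
        The model family: memory bounds in steps, ``FULL`` (None) for the
        unrestricted model.  Must include 0 (the no-memory baseline).
    """

    def __init__(self, target: SpatioTemporalCube,
                 drivers: dict[str, SpatioTemporalCube],
                 statics: StaticFieldSet | None = None,
                 biomes: BiomeMap | None = None,
                 memory_lengths=(FULL, 0),
                 model_config: nn.ModelConfig | None = None,
                 k_spatial: int = 4, block: int = 5,
                 k_temporal: int | None = None, fold_years: int | None = None,
                 overlap_years: int = 1,
                 repetitions: int = 1,
                 retained: np.ndarray | None = None):
        if 0 not in [m for m in memory_lengths if m is not FULL]:
            raise ValueError("memory_lengths must include the M_0 baseline")
        self.target = target
        self.drivers = drivers
        self.statics = statics
        self.memory_lengths = tuple(memory_lengths)
        n_feat = len(drivers) + (len(statics.names) if statics else 0)
        self.model_config = model_config or nn.ModelConfig(n_features=n_feat)
        self.k_spatial = k_spatial
        self.block = block
        years = target.time.n_years
        if k_temporal is None:
            k_temporal, fold_years, overlap_years = _default_temporal(years)
        elif fold_years is None:
            num = years + (k_temporal - 1) * overlap_years
            if num % k_temporal:
                raise ValueError(
                    f"{k_temporal} folds with overlap {overlap_years} do not "
                    f"tile {years} years")
            fold_years = num // k_temporal
        self.temporal_folds = crossval.make_temporal_folds(
            total_years=years, fold_years=fold_years,
            overlap_years=overlap_years, k=k_temporal,
            start_year=target.time.start_year)
        self.repetitions = repetitions
        if retained is None:
            if statics is not None and "water_frac" in statics and \
                    "barren_frac" in statics:
                retained = filter_pixels(target, statics)
            else:
                retained = target.valid.mean(axis=1) >= 0.5
        self.retained = np.asarray(retained, bool)
        self.biomes = biomes or BiomeMap(
            np.zeros(target.n_pixels, int), target.lat, self.retained)

    @classmethod
    def from_synthetic(cls, cfg: SyntheticConfig | None = None,
                       **kwargs) -> "MemoryEffectModel":
        """Build model and data from the synthetic generator in one step."""
        cfg = cfg or SyntheticConfig()
        drivers, statics = gen_drivers(cfg)
        target, _ = gen_vegetation(drivers, cfg)
        return cls(target, drivers, statics, **kwargs)

    def fit(self, seed: int = 0) -> "MemoryEffectResults":
        """Train the model family under blocked cross-validation."""
        rng = np.random.default_rng(seed)
        plan = crossval.make_plan(
            k_spatial=self.k_spatial, k_temporal=len(self.temporal_folds),
            repetitions=self.repetitions, rng=rng, block=self.block)
        rep_preds: dict = {}
        for n in self.memory_lengths:
            log.info("fitting %s (%d runs)", model_label(n), len(plan))
            rep_preds[n] = crossval.run_memory_model(
                self.target, self.drivers, self.statics, self.retained,
                plan, self.temporal_folds, n, self.model_config,
                seed=int(rng.integers(0, 2**31)), block=self.block)
        return MemoryEffectResults(self, rep_preds)


@dataclass
class MemoryEffectResults:
    """Fitted memory-effect analysis.

    Holds per-repetition and median cross-validated predictions for every
    model of the family, per-decomposition metric tables, pixel maps of
    explained variance, and the memory statistics derived from them.
    """

    model: MemoryEffectModel
    rep_predictions: dict  # n -> (R, P, T) with NaN outside test coverage

    def __post_init__(self) -> None:
        self.predictions = {
            n: crossval.aggregate_repetitions(p)
            for n, p in self.rep_predictions.items()
        }
        tgt = self.model.target
        retained = self.model.retained
        obs_masked = tgt.masked()
        obs_masked[~retained] = np.nan
        self.obs_parts = self._parts_from(obs_masked)
        self.pred_parts = {
            n: self._parts_from(np.where(retained[:, None], p, np.nan))
            for n, p in self.predictions.items()
        }
        self.pixel_r2 = {
            d: {n: pixel_r_squared(self.obs_parts[d], self.pred_parts[n][d])
                for n in self.predictions}
            for d in DECOMPS
        }
        self.metric_table = self._metric_table()

    # -- decomposition ---------------------------------------------------

    def _parts_from(self, arr: np.ndarray) -> dict[str, np.ndarray]:
        tgt = self.model.target
        cube = SpatioTemporalCube.from_masked(
            arr, tgt.lat, tgt.lon, tgt.time, tgt.grid_shape)
        dec = decompose(cube)
        return {"RAW": cube.masked(), "MSC": dec.msc_tiled(),
                "ANO": dec.ano.masked()}

    # -- metrics ---------------------------------------------------------

    def _metric_table(self) -> pd.DataFrame:
        rows = []
        biomes = self.model.biomes
        w = self.model.target.area_weights()
        for d in DECOMPS:
            for n in self.predictions:
                bt = biome_metrics(self.obs_parts[d], self.pred_parts[n][d],
                                   biomes, weights=w)
                for _, r in bt.iterrows():
                    rows.append({"level": "biome", "decomposition": d,
                                 "model": model_label(n), "biome": int(r.biome),
                                 "r2": r.r2, "rmse": r.rmse, "area": r.area})
                if len(bt):
                    rows.append({
                        "level": "global", "decomposition": d,
                        "model": model_label(n), "biome": -1,
                        "r2": global_metric(bt.r2.values, bt.area.values),
                        "rmse": global_metric(bt.rmse.values, bt.area.values),
                        "area": float(bt.area.sum()),
                    })
        return pd.DataFrame(rows)

    def global_r2(self, n, decomposition: str = "RAW") -> float:
        t = self.metric_table
        row = t[(t.level == "global") & (t.decomposition == decomposition)
                & (t.model == model_label(n))]
        return float(row.r2.iloc[0])

    def mem_global(self, n=FULL, decomposition: str = "RAW") -> float:
        """Mem_n = R2_n - R2_0 on the biome-area weighted global metric."""
        return float(mem(self.global_r2(n, decomposition),
                         self.global_r2(0, decomposition),
                         model_label(n)).value)

    def mem_map(self, n=FULL, decomposition: str = "RAW") -> np.ndarray:
        """Per-pixel Mem_n map."""
        return mem(self.pixel_r2[decomposition][n],
                   self.pixel_r2[decomposition][0], model_label(n)).value

    def pooled(self, n, decomposition: str = "RAW",
               variant: str = "nse") -> dict[str, float]:
        return pooled_metrics(self.obs_parts[decomposition],
                              self.pred_parts[n][decomposition],
                              variant=variant)

    # -- inference -------------------------------------------------------

    def significance(self, n=FULL, n_perm: int = 999, alpha: float = 0.1,
                     rng: np.random.Generator | None = None
                     ) -> SignificanceResult:
        """Max-statistic permutation test of Mem_n against the M_0 baseline."""
        obs = self.obs_parts["RAW"]
        return max_stat_test(self.rep_predictions[n], self.rep_predictions[0],
                             obs, n_perm=n_perm, alpha=alpha, rng=rng)

    # -- summaries -------------------------------------------------------

    def memory_curve(self, decomposition: str = "RAW") -> pd.DataFrame:
        return summaries.memory_curve(self.pixel_r2[decomposition],
                                      self.model.biomes)

    def climate_space(self, temp_edges, precip_edges, n=FULL,
                      decomposition: str = "ANO", min_count: int = 10):
        tmean = self.model.drivers["tmean"].masked().mean(axis=1)
        spy = self.model.target.time.steps_per_year
        precip = self.model.drivers["precip"].masked().mean(axis=1) * spy
        return summaries.climate_space(
            self.mem_map(n, decomposition), tmean, precip,
            temp_edges, precip_edges, min_count=min_count)

    def monthly_memory(self, min_pixels: int = 10) -> pd.DataFrame:
        return summaries.monthly_memory(
            self.model.target, self.predictions[FULL], self.predictions[0],
            self.model.biomes, min_pixels=min_pixels)

    def regional_example(self, bbox) -> pd.DataFrame:
        preds = {model_label(n): p for n, p in self.predictions.items()}
        return summaries.regional_example(self.model.target, preds, bbox)

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of global skill and memory effects."""
        m = self.model
        lines = [
            "Memory-effect analysis".center(70),
            "=" * 70,
            f"pixels retained: {int(m.retained.sum())}/{m.target.n_pixels}"
            f"   steps: {m.target.n_steps}"
            f"   repetitions: {m.repetitions}",
            f"models: {', '.join(model_label(n) for n in self.predictions)}"
            f"   spatial folds: {m.k_spatial} (block {m.block})"
            f"   temporal folds: {len(m.temporal_folds)}",
            "-" * 70,
            f"{'decomp':<8}{'model':<10}{'R2_global':>12}{'RMSE_global':>14}"
            f"{'Mem':>10}",
        ]
        for d in DECOMPS:
            for n in self.predictions:
                r2 = self.global_r2(n, d)
                t = self.metric_table
                row = t[(t.level == "global") & (t.decomposition == d)
                        & (t.model == model_label(n))]
                rm = float(row.rmse.iloc[0])
                memv = "" if n == 0 else f"{self.mem_global(n, d):>10.3f}"
                lines.append(
                    f"{d:<8}{model_label(n):<10}{r2:>12.3f}{rm:>14.3f}{memv}")
        lines.append("=" * 70)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<MemoryEffectResults: {len(self.predictions)} models, "
                f"{self.model.repetitions} repetitions>")
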