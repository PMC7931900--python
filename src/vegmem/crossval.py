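"""Spatio-temporal blocked cross-validation: planning and execution.

Spatial blocking assigns contiguous ``block x block`` pixel tiles (anchor
randomized per repetition) to ``k`` spatial folds so that spatially
autocorrelated neighbours never straddle a train/test boundary.  Temporal
blocking splits the record into ``k`` spans overlapping by a warmup year in
which the recurrent state spins up from zero; warmup steps are excluded from
both the training loss and the evaluation.  Per repetition, every retained
pixel's non-warmup steps are predicted exactly once; the final prediction is
the median over repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .grid import SpatioTemporalCube, StaticFieldSet, TimeAxis
from .permute import FULL, apply_scheme, make_scheme, model_label
from .preprocess import standardize

log = logging.getLogger(__name__)

__all__ = [
    "TemporalFold", "RunConfig",
    "make_spatial_folds", "make_temporal_folds", "make_plan",
    "aggregate_repetitions", "run_memory_model",
]


@dataclass(frozen=True)
class TemporalFold:
    index: int
    start_year: int
    end_year: int        # exclusive
    warmup_years: int = 1

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year

    def step_slice(self, axis: TimeAxis) -> slice:
        return axis.year_slice(self.start_year, self.end_year)

    def warmup_steps(self, axis: TimeAxis) -> np.ndarray:
        """Warmup flags per step within the fold's own span."""
        n = self.n_years * axis.steps_per_year
        w = np.zeros(n, dtype=bool)
        w[: self.warmup_years * axis.steps_per_year] = True
        return w


@dataclass
class RunConfig:
    """One cross-validation run: spatial fold roles and a test temporal fold."""

    repetition: int
    train_spatial: tuple[int, ...]
    val_spatial: int
    test_spatial: int
    test_temporal: int
    anchor: tuple[int, int]
    spatial_seed: int

    def __post_init__(self) -> None:
        roles = set(self.train_spatial) | {self.val_spatial, self.test_spatial}
        if len(roles) != len(self.train_spatial) + 2:
            raise ValueError("spatial fold roles must be disjoint")


def make_spatial_folds(grid_shape: tuple[int, int], retained: np.ndarray,
                       block: int = 5, k: int = 4,
                       anchor: tuple[int, int] = (0, 0),
                       rng: np.random.Generator | None = None,
                       max_retries: int = 50) -> np.ndarray:
    """Assign every pixel a spatial fold id in 1..k via randomized block tiling.

    Tiling starts at ``anchor`` (row/col offsets within [0, block)); edge
    fragments form their own smaller blocks.  Each block is assigned to one
    fold uniformly at random; the draw is repeated (up to ``max_retries``)
    until every fold holds at least one retained pixel.
    """
    if k < 3:
        raise ValueError("need k >= 3 spatial folds for train/val/test roles")
    rng = rng or np.random.default_rng()
    h, w = grid_shape
    retained = np.asarray(retained, bool).reshape(h, w)
    ar, ac = anchor[0] % block, anchor[1] % block
    row_edges = np.unique(np.r_[0, np.arange(ar, h, block), h])
    col_edges = np.unique(np.r_[0, np.arange(ac, w, block), w])
    n_blocks = (len(row_edges) - 1) * (len(col_edges) - 1)
    for _ in range(max_retries):
        assign = rng.integers(1, k + 1, size=n_blocks)
        fold = np.zeros((h, w), dtype=int)
        b = 0
        for i in range(len(row_edges) - 1):
            for j in range(len(col_edges) - 1):
                fold[row_edges[i]:row_edges[i + 1],
                     col_edges[j]:col_edges[j + 1]] = assign[b]
                b += 1
        present = np.unique(fold[retained])
        if present.size == k:
            return fold.ravel()
    raise RuntimeError(
        f"could not populate all {k} spatial folds with retained pixels "
        f"after {max_retries} draws; grid too small for block={block}"
    )


def make_temporal_folds(total_years: int = 33, fold_years: int = 9,
                        overlap_years: int = 1, k: int = 4,
                        start_year: int = 1983) -> list[TemporalFold]:
    """Overlapping temporal spans tiling the record.

    ``k`` folds of ``fold_years`` years, consecutive folds sharing
    ``overlap_years`` warmup years, must satisfy
    ``k * fold_years - (k - 1) * overlap_years == total_years``.
    """
    if k * fold_years - (k - 1) * overlap_years != total_years:
        raise ValueError(
            f"{k} folds of {fold_years} years overlapping by {overlap_years} "
            f"do not tile {total_years} years"
        )
    stride = fold_years - overlap_years
    return [
        TemporalFold(index=i + 1,
                     start_year=start_year + i * stride,
                     end_year=start_year + i * stride + fold_years,
                     warmup_years=overlap_years)
        for i in range(k)
    ]


def make_plan(k_spatial: int = 4, k_temporal: int = 4, repetitions: int = 10,
              rng: np.random.Generator | None = None, block: int = 5,
              rotations: int | None = None) -> list[RunConfig]:
    """The full run schedule: rotations x temporal folds x repetitions.

    Spatial fold roles rotate cyclically so that each fold serves as the test
    fold exactly once per repetition; requesting fewer rotations than
    ``k_spatial`` would leave pixels never tested and is rejected.
    """
    if k_spatial < 3:
        raise ValueError("need at least 3 spatial folds")
    rotations = k_spatial if rotations is None else rotations
    if rotations != k_spatial:
        raise ValueError(
            f"{rotations} role rotations cannot cover all {k_spatial} spatial "
            f"folds as test sets; coverage would be violated"
        )
    rng = rng or np.random.default_rng()
    plan: list[RunConfig] = []
    for rep in range(1, repetitions + 1):
        anchor = (int(rng.integers(0, block)), int(rng.integers(0, block)))
        seed = int(rng.integers(0, 2**31 - 1))
        for rot in range(k_spatial):
            test = rot + 1
            val = (rot + 1) % k_spatial + 1
            train = tuple(f for f in range(1, k_spatial + 1)
                          if f not in (test, val))
            for tf in range(1, k_temporal + 1):
                plan.append(RunConfig(
                    repetition=rep, train_spatial=train, val_spatial=val,
                    test_spatial=test, test_temporal=tf,
                    anchor=anchor, spatial_seed=seed,
                ))
    return plan


def aggregate_repetitions(preds: np.ndarray) -> np.ndarray:
    """Elementwise median over the repetition axis of an (R, P, T) array.

    Cells missing a prediction in any repetition come out NaN (invalid).
    """
    preds = np.asarray(preds, float)
    if preds.ndim != 3 or preds.shape[0] == 0:
        raise ValueError("need a non-empty (repetition, pixel, time) array")
    return np.median(preds, axis=0)


# ---------------------------------------------------------------------------
# Execution

def _feature_stack(drivers: dict[str, SpatioTemporalCube],
                   statics: StaticFieldSet | None,
                   static_names: list[str] | None = None
                   ) -> tuple[np.ndarray, list[str], int]:
    """(P, T, F) raw feature stack; returns names and the dynamic count."""
    dyn_names = list(drivers)
    arrs = [drivers[k].values for k in dyn_names]
    p, t = arrs[0].shape
    stack = [a[:, :, None] for a in arrs]
    names = list(dyn_names)
    if statics is not None:
        static_names = static_names or statics.names
        for s in static_names:
            stack.append(np.broadcast_to(statics[s][:, None, None], (p, t, 1)))
            names.append(s)
    return np.concatenate(stack, axis=2), names, len(dyn_names)


def _standardize_features(x: np.ndarray, names: list[str],
                          train_pixels: np.ndarray, train_steps: np.ndarray
                          ) -> np.ndarray:
    """Per-variable standardization fitted on the training selection only."""
    out = np.empty_like(x)
    for j, name in enumerate(names):
        ref = x[np.ix_(train_pixels, train_steps)][:, :, j]
        m = float(ref.mean())
        s = float(ref.std())
        if s == 0.0:
            raise ValueError(f"zero-variance predictor {name!r} on training data")
        out[:, :, j] = (x[:, :, j] - m) / s
    return out


def run_memory_model(
    target: SpatioTemporalCube,
    drivers: dict[str, SpatioTemporalCube],
    statics: StaticFieldSet | None,
    retained: np.ndarray,
    plan: list[RunConfig],
    temporal_folds: list[TemporalFold],
    n,
    model_cfg: nn.ModelConfig,
    seed: int = 0,
    block: int = 5,
) -> np.ndarray:
    """Execute every run of ``plan`` for memory bound ``n``.

    Returns an (repetitions, pixel, time) array of test predictions; entries
    outside a repetition's test coverage (warmup steps, unretained pixels)
    are NaN.
    """
    axis = target.time
    reps = sorted({r.repetition for r in plan})
    x_raw, names, _ = _feature_stack(drivers, statics)
    y_all = target.masked()
    out = np.full((len(reps), target.n_pixels, target.n_steps), np.nan)
    rep_index = {r: i for i, r in enumerate(reps)}
    grid_shape = target.grid_shape
    if grid_shape is None:
        raise ValueError("cross-validation needs a 2-D grid layout")
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(len(plan))

    fold_cache: dict[tuple, np.ndarray] = {}
    for run_i, run in enumerate(plan):
        key = (run.repetition, run.anchor, run.spatial_seed)
        if key not in fold_cache:
            fold_cache[key] = make_spatial_folds(
                grid_shape, retained, block=block,
                k=len(run.train_spatial) + 2, anchor=run.anchor,
                rng=np.random.default_rng(run.spatial_seed),
            )
        spatial = fold_cache[key]
        run_rng = np.random.default_rng(int(run_seeds[run_i]) % (2**31))

        test_fold = temporal_folds[run.test_temporal - 1]
        train_folds = [f for f in temporal_folds if f.index != test_fold.index]
        train_pix = np.flatnonzero(retained & np.isin(spatial, run.train_spatial))
        val_pix = np.flatnonzero(retained & (spatial == run.val_spatial))
        test_pix = np.flatnonzero(retained & (spatial == run.test_spatial))

        train_step_mask = np.zeros(axis.n_steps, bool)
        for f in train_folds:
            sl = f.step_slice(axis)
            w = f.warmup_steps(axis)
            train_step_mask[sl] = train_step_mask[sl] | ~w
        x = _standardize_features(
            x_raw, names, train_pix, np.flatnonzero(train_step_mask))

        spans = []
        for f in train_folds:
            sl = f.step_slice(axis)
            spans.append((sl, f.warmup_steps(axis)))
        bsz = model_cfg.batch_size

        def train_batches(rng, spans=spans, x=x, train_pix=train_pix):
            order = rng.permutation(train_pix)
            for sl, warm in spans:
                T = sl.stop - sl.start
                for i0 in range(0, order.size, bsz):
                    pix = order[i0:i0 + bsz]
                    scheme = make_scheme(T, n, rng)
                    xb, yb = apply_scheme(x[pix, sl], y_all[pix, sl], scheme)
                    mask = (scheme.loss_mask[None, :]
                            & ~warm[scheme.order][None, :]
                            & np.isfinite(yb))
                    yield xb, np.nan_to_num(yb), mask

        tsl = test_fold.step_slice(axis)
        twarm = test_fold.warmup_steps(axis)
        val_batches = []
        for i0 in range(0, val_pix.size, bsz):
            pix = val_pix[i0:i0 + bsz]
            yv = y_all[pix, tsl]
            mask = ~twarm[None, :] & np.isfinite(yv)
            val_batches.append((x[pix, tsl], np.nan_to_num(yv), mask))

        cfg = nn.ModelConfig(**{**model_cfg.__dict__,
                                "n_features": x.shape[2],
                                "seed": int(run_seeds[run_i]) % (2**31)})
        model = nn.build_model(cfg)
        nn.train(model, train_batches, val_batches, cfg, rng=run_rng)

        warm_n = int(twarm.sum())
        for i0 in range(0, test_pix.size, bsz):
            pix = test_pix[i0:i0 + bsz]
            pred, ok = nn.predict(model, x[pix, tsl], warmup_steps=warm_n)
            cols = np.arange(tsl.start + warm_n, tsl.stop)
            out[rep_index[run.repetition]][np.ix_(pix, cols)] = pred[:, warm_n:]
        log.info("run %d/%d (%s rep %d, test fold s%d/t%d) done: %d epochs",
                 run_i + 1, len(plan), model_label(n), run.repetition,
                 run.test_spatial, run.test_temporal, len(model.history))
    return out
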