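"""Pixelwise permutation test for memory effects with max-statistic FWER control.

Under the null hypothesis that the full-memory and no-memory models perform
equally, each repetition's prediction series is exchangeable between the two
labels.  The test permutes the M_0/M_full labels repetition-wise — the same
swap pattern applied to all pixels simultaneously, preserving the spatial
dependence structure — recomputes the per-pixel memory effect Mem for every
permutation, and records the maximum of |Mem| over pixels.  The significance
threshold is the (1 - alpha) quantile of this maximum-statistic distribution
(observed value pooled in), which controls the family-wise error rate across
pixels.  When the number of distinct swap patterns 2^R does not exceed the
requested permutation count, all patterns are enumerated (exact test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import pixel_r_squared

__all__ = ["SignificanceResult", "permute_labels", "max_stat_test",
           "null_fwer"]


@dataclass
class SignificanceResult:
    mem: np.ndarray              # observed per-pixel Mem
    p_values: np.ndarray         # per-pixel permutation p-values
    max_distribution: np.ndarray  # max over pixels of |Mem|, per permutation
    threshold: float
    significant: np.ndarray      # |Mem| > threshold
    alpha: float
    n_perm: int                  # permutations evaluated (observed included)
    exact: bool

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.any())


def _check_labeled(preds_full: np.ndarray, preds_0: np.ndarray) -> None:
    if preds_full.shape != preds_0.shape:
        raise ValueError(
            "labels are unbalanced: need equal (repetition, pixel, time) "
            f"shapes, got {preds_full.shape} vs {preds_0.shape}"
        )
    if preds_full.ndim != 3:
        raise ValueError("predictions must be (repetition, pixel, time)")


def permute_labels(preds_full: np.ndarray, preds_0: np.ndarray,
                   rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomly swap the M_full/M_0 labels of whole repetitions.

    A fair coin per repetition decides whether its two labelled prediction
    sets trade places; the same swap applies to every pixel.  Returns the
    relabelled arrays and the swap pattern.
    """
    preds_full = np.asarray(preds_full, float)
    preds_0 = np.asarray(preds_0, float)
    _check_labeled(preds_full, preds_0)
    swap = rng.random(preds_full.shape[0]) < 0.5
    return (_relabel(preds_full, preds_0, swap),
            _relabel(preds_0, preds_full, swap), swap)


def _relabel(a: np.ndarray, b: np.ndarray, swap: np.ndarray) -> np.ndarray:
    out = a.copy()
    out[swap] = b[swap]
    return out


def _mem_map(preds_full: np.ndarray, preds_0: np.ndarray, obs: np.ndarray,
             swap: np.ndarray, variant: str) -> np.ndarray:
    """Per-pixel Mem after applying a label-swap pattern."""
    f = _relabel(preds_full, preds_0, swap)
    z = _relabel(preds_0, preds_full, swap)
    med_f = np.nanmedian(f, axis=0)
    med_z = np.nanmedian(z, axis=0)
    return (pixel_r_squared(obs, med_f, variant)
            - pixel_r_squared(obs, med_z, variant))


def max_stat_test(preds_full: np.ndarray, preds_0: np.ndarray,
                  obs: np.ndarray, n_perm: int = 999, alpha: float = 0.1,
                  rng: np.random.Generator | None = None,
                  variant: str = "corr2") -> SignificanceResult:
    """Max-|Mem| permutation test over all pixels.

    ``preds_full`` / ``preds_0`` are (repetition, pixel, time) prediction
    arrays for the two labels, ``obs`` the (pixel, time) observations (NaN =
    missing).  The observed Mem uses the median over repetitions per label.
    P-values compare each pixel's |Mem| against its own permutation values;
    the significance mask thresholds |Mem| at the (1 - alpha) quantile of the
    max-statistic distribution.
    """
    preds_full = np.asarray(preds_full, float)
    preds_0 = np.asarray(preds_0, float)
    obs = np.asarray(obs, float)
    _check_labeled(preds_full, preds_0)
    R = preds_full.shape[0]
    if R < 2:
        raise ValueError("need at least 2 repetitions per label")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng or np.random.default_rng()

    exact = 2**R <= n_perm
    if exact:
        patterns = [
            np.array([(i >> r) & 1 for r in range(R)], dtype=bool)
            for i in range(2**R)
        ]
    else:
        patterns = [np.zeros(R, dtype=bool)]  # identity = observed
        patterns += [rng.random(R) < 0.5 for _ in range(n_perm)]

    mems = np.stack([
        _mem_map(preds_full, preds_0, obs, sw, variant) for sw in patterns
    ])  # (n_patterns, P)
    observed = mems[0]
    abs_mems = np.abs(mems)
    with np.errstate(all="ignore"):
        max_dist = np.nanmax(abs_mems, axis=1)

    obs_abs = np.abs(observed)
    cnt = np.nansum(abs_mems >= obs_abs[None, :], axis=0)
    p_values = cnt / len(patterns)
    p_values = np.where(np.isfinite(observed), p_values, np.nan)

    threshold = float(np.nanquantile(max_dist, 1.0 - alpha))
    significant = np.where(np.isfinite(observed), obs_abs > threshold, False)
    return SignificanceResult(
        mem=observed, p_values=p_values, max_distribution=max_dist,
        threshold=threshold, significant=significant, alpha=alpha,
        n_perm=len(patterns), exact=exact,
    )


def null_fwer(n_datasets: int = 200, n_pixels: int = 100, n_steps: int = 48,
              reps_per_label: int = 4, n_perm: int = 999, alpha: float = 0.1,
              pred_noise: float = 0.5,
              rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo family-wise error rate of the test under a global null.

    Every dataset draws both labels' per-repetition predictions from the same
    distribution (observations plus independent noise), so any significant
    pixel is a false discovery.  Returns the fraction of datasets with at
    least one significant pixel; with the threshold at the (1 - alpha)
    quantile of the max-statistic distribution this estimates the FWER.

    Note the attainable rejection levels are multiples of
    ``1 / 2**(reps_per_label - 1)``: the exact test enumerates sign-symmetric
    swap patterns, so with 4 repetitions per label the rate closest to a
    nominal 0.1 is 1/8.
    """
    rng = rng or np.random.default_rng()
    hits = 0
    for _ in range(n_datasets):
        obs = rng.normal(size=(n_pixels, n_steps))
        pf = obs[None] + rng.normal(
            0, pred_noise, size=(reps_per_label, n_pixels, n_steps))
        p0 = obs[None] + rng.normal(
            0, pred_noise, size=(reps_per_label, n_pixels, n_steps))
        res = max_stat_test(pf, p0, obs, n_perm=n_perm, alpha=alpha, rng=rng)
        hits += int(res.any_significant)
    return hits / n_datasets
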