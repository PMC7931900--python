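# vegmem

Quantifying **memory effects** of climate drivers on vegetation state with
memory-bounded recurrent sequence models.

Vegetation greenness (an NDVI-like proxy, 15-daily, gridded) responds to
climate not only instantaneously but through temporally lagged pathways —
soil-water storage, phenology, accumulated temperature. `vegmem` measures how
much of the predictable variation in vegetation state requires access to
*antecedent* driver conditions, and on what time scale, without attributing
the effect to any single driver:

1. A sequence regressor (fully connected encoder → LSTM → linear head) maps
   per-step climate drivers plus static soil/land-cover fields to the
   vegetation proxy.
2. A family of models **M_n** is trained in which the usable ordered history
   is bounded to *n* steps (n × 15 days) by **block permutation**: during
   training, features and target are shuffled in unison in blocks of n + 1
   consecutive steps, and only block-final positions — which retain exactly
   their n true antecedents in order — enter the loss. M₀ permutes every step
   (no memory); M_full trains on intact series.
3. Models are compared under a **spatio-temporal blocked cross-validation**
   (5 × 5-pixel spatial blocks in 4 folds; overlapping multi-year temporal
   folds whose shared year is the recurrent warmup), so spatial and temporal
   autocorrelation cannot leak between training and test.
4. The memory effect is **Mem_n = R²(M_n) − R²(M₀)**, computed per pixel, per
   hydro-climatic biome (on pixel-area weighted biome-mean series) and
   globally (biome-area weighted: R²_global = (1/A) Σ_b R²_b·A_b), for the
   raw series (RAW), the median seasonal cycle (MSC) and the anomalies (ANO).
5. Pixelwise significance of Mem is assessed by a **max-statistic permutation
   test**: M₀/M_full labels are swapped repetition-wise (the same swap for
   all pixels, preserving spatial dependence), and each pixel's |Mem| is
   thresholded at the 90th percentile of the permutation distribution of
   max over pixels of |Mem|, which controls the family-wise error rate.

A synthetic-data module generates driver and vegetation cubes whose memory
structure is known (a leaky soil-water store with persistence τ), so the
whole chain — training, cross-validation, metrics, significance — is testable
end to end without any satellite or reanalysis downloads.

## Worked example

```python
import numpy as np
from vegmem import MemoryEffectModel, ModelConfig, FULL
from vegmem.synthetic import SyntheticConfig

model = MemoryEffectModel.from_synthetic(
    SyntheticConfig(height=8, width=8, years=5, tau=3.0, seed=2),
    memory_lengths=(FULL, 0),
    model_config=ModelConfig(n_features=1, fc_layers=1, fc_width=16,
                             lstm_hidden=16, max_epochs=40, patience=6,
                             batch_size=10, learning_rate=0.01),
    block=2, repetitions=1)
results = model.fit(seed=5)
print(results.summary())
```

```
                        Memory-effect analysis
======================================================================
pixels retained: 64/64   steps: 120   repetitions: 1
models: M_full, M_0   spatial folds: 4 (block 2)   temporal folds: 4
----------------------------------------------------------------------
decomp  model        R2_global   RMSE_global       Mem
RAW     M_full           0.904         0.007     0.337
RAW     M_0              0.567         0.017
MSC     M_full           0.858         0.009     0.778
MSC     M_0              0.080         0.020
ANO     M_full           0.692         0.010     0.511
ANO     M_0              0.180         0.022
======================================================================
```

The `Mem` column is the gain in biome-area-weighted explained variance from
allowing the model unrestricted temporal context: here the τ = 3 soil store
makes antecedent precipitation genuinely informative, so M_full clearly beats
M₀ on the raw series, the seasonal cycle and the anomalies.  (At this desk
scale — 64 pixels, 5 years, a 16-unit model — the absolute numbers are noisy;
the sign and ordering of the effects are the reproducible part.)
`results.memory_curve()`, `results.significance()`,
`results.climate_space(...)` and `results.monthly_memory()` give the
per-biome memory-length curves, the pixelwise permutation test, the
climate-space binning and the per-month across-year decomposition.

A config-driven CLI wraps the same pipeline
(`vegmem all --config config.yml`), with stages `simulate`, `preprocess`,
`crossval`, `metrics`, `significance`, `summarize`, a checksummed run
manifest, and skip-on-rerun idempotence.

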