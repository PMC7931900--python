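# Methods

This note documents the models and procedures implemented in `vegmem`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the package's numerical conventions and limitations.

## Data model

All gridded inputs live on a flat pixel axis: a cube is a `(pixel, time)`
value array with a boolean validity mask, per-pixel latitude/longitude, and
a regular calendar of `steps_per_year` equal steps (default 24, i.e. two
steps per calendar month; a 15-daily grid is represented this way, so exact
day-of-month boundaries are not modelled).  Time indices are 0-based and
ranges are half-open.  Files on a `(lat, lon, time)` grid are flattened on
read and the 2-D layout is kept as `grid_shape` for spatial blocking.
Pixel-area weights are cos(latitude of the pixel center), the standard
equal-angle-grid approximation; they are relative weights, so only ratios
matter.

Preprocessing follows three screening rules with strict "more than"
boundaries: a coarse pixel-time-step is dropped when more than 50 % of the
fine cells in its aggregation block are missing; a pixel is dropped when
more than 50 % of its time series is missing, when its water land-cover
fraction exceeds 20 %, or when its barren fraction exceeds 50 %.  Exactly-
at-threshold cases are kept.

The target decomposition: the median seasonal cycle (MSC) is the per-pixel
median over years of each step-of-year, computed on valid entries; the
anomaly (ANO) is the raw value minus the tiled MSC.  The decomposition is
applied identically, and separately, to observations and to model
predictions (a prediction's MSC is the median of the *predicted* years, not
the observed climatology).  Wherever raw, MSC and ANO are all valid,
`raw = msc + ano` holds exactly.

## Sequence model

The regressor is a per-step encoder (default 2 fully connected layers of
128 units, ReLU, dropout 0.1 after each) feeding a single LSTM layer
(default hidden size 256) and a linear head that maps the hidden state to
one scalar per step.  Inputs are the dynamic drivers concatenated with the
static fields, all standardized to zero mean / unit variance using
statistics computed on the training selection only (training pixels ×
training steps), to avoid leaking test-period information; the fitted
transform is reused unchanged at validation and prediction time.

Training minimizes mean squared error over the steps selected by a loss
mask, with Adam (learning rate 0.001 by default, mini-batches of 20 pixel
sequences) and early stopping on a validation loss (default patience 10
epochs, best parameters restored).  The implementation is plain numpy with
hand-written backpropagation through time; gradients are verified against
central finite differences in the test suite.  Hidden and cell state start
at zero for every sequence, which is why each temporal fold carries a
warmup year: warmup steps are excluded from the training loss as well as
from evaluation, since predictions made from an un-spun-up state do not
reflect the model's steady behaviour.  The forget-gate bias is initialized
to 1 (a standard choice that eases learning of long retention).  Dropout is
active only during training; prediction is deterministic.

For the scaled-down experiments used in the tests the same architecture is
shrunk (encoder width 32, hidden 32, batch 10) and the learning rate raised
to 0.01: with only tens of pixel sequences per fold, an epoch contains very
few optimizer steps, and the larger step size reaches convergence within a
50-epoch budget.  These are the package's small-problem defaults, chosen by
convergence behaviour on synthetic data.

## Memory bounding by block permutation

Model M_n is trained on series permuted in blocks of n + 1 consecutive
steps: a fresh scheme is drawn for every mini-batch with a block offset
uniform on {0, …, n} (so block boundaries vary between draws), complete
blocks are shuffled uniformly, and only the last element of each complete
block enters the loss — that position has exactly its n true antecedents,
in original order, immediately before it.  Incomplete leading/trailing
fragments take part in the shuffle but are entirely loss-masked, since
their elements lack n ordered antecedents.  Dynamic features and target are
permuted in unison; static features are constant per step and therefore
unaffected.  Validation and prediction always use intact series.

Two special cases: n = 0 shuffles every step independently (the model can
use only concurrent drivers — and the marginal distribution of past values,
which the permutation preserves); n = FULL applies no permutation.  The
warmup exclusion composes with the scheme: a position contributes to the
loss only if it is block-final *and* its original time step is outside the
warmup.  One scheme is shared by all sequences of a mini-batch (drawing per
sequence would multiply scheme-generation cost without changing what the
model can learn; the per-batch reading of "a fresh permutation at each
training step" is the implemented choice).

The bound is a *training-time* restriction: at prediction time the model
consumes the intact series, so a model trained as M_n may carry state
further than n steps; what it cannot have learned is any mapping that
requires more than n steps of ordered history.

## Cross-validation design

Spatial blocking tiles the grid with `block × block` (default 5 × 5) pixel
squares, anchored at a random offset, each square assigned uniformly to one
of 4 spatial folds; per run, 2 folds train, 1 validates (early stopping), 1
is tested.  Temporal blocking splits the record into k spans of L years
overlapping by one warmup year, requiring `k·L − (k−1)·overlap = total`
(33 years → 4 spans of 9).  The test span serves validation and test
simultaneously — they differ spatially, not temporally.  Roles rotate
cyclically so each spatial fold is the test fold exactly once per
repetition, and each temporal fold is the test span once per rotation:
one repetition therefore predicts every retained pixel's non-warmup steps
exactly once, and with the defaults (4 × 4 × 10 repetitions) the schedule
has 160 runs.  Anchor and fold assignment are redrawn per repetition, and
the final prediction is the element-wise median over repetitions.  If a
random assignment leaves a spatial fold without retained pixels (possible
on tiny grids) it is redrawn up to a retry limit.

Leakage guards, enforced by tests: no training pixel shares a spatial block
with a test pixel of the same run, and training-loss years never intersect
evaluated test years (only declared warmup years are shared between spans).

## Metrics and the memory statistic

Two R² variants are provided.  The default is the squared Pearson
correlation (`corr2`), bounded in [0, 1] and insensitive to affine bias —
appropriate for comparing temporal tracking, and the variant under which a
handful of weakly anti-correlated pixels cannot produce misleading negative
skill.  Nash–Sutcliffe efficiency (`nse`, 1 − SSE/SST) is available for
pooled headline numbers where bias should count.  Metrics use only time
steps valid in both observation and prediction, require at least 3 pairs
and non-degenerate variance, and return NaN (flagged undefined) otherwise.

Aggregation is two-stage: pixel series are combined into biome-mean series
with cos-latitude weights (observations and predictions separately), scored
per biome, then combined globally with biome-area weights.  Biome areas are
computed from retained pixels only (recorded in output provenance).  An
optional mean-removal flag subtracts each pixel's time mean first, removing
purely spatial variance from the skill.  The memory effect is
`Mem_n = R²(M_n) − R²(M₀)`; it may legitimately be negative (a globally
trained model can trade off regions), and `Mem` without subscript refers to
M_full vs M₀.

## Significance: max-statistic permutation test

Under the null that M_full and M₀ perform equally, each repetition's pair
of prediction series is exchangeable between the labels.  The test swaps
labels repetition-wise — one fair coin per repetition, the same swap applied
to all pixels simultaneously, which preserves the spatial dependence of the
statistic map.  Per pattern, each pixel's Mem is recomputed from the
label-respecting medians over repetitions, and the maximum over pixels of
|Mem| is recorded; the pixel significance threshold is the (1 − α) quantile
(α = 0.1 → 90th percentile) of this maximum-statistic distribution with the
observed value pooled in, giving family-wise error control.  Per-pixel
p-values compare each pixel's own |Mem| against its permutation values,
with the observed statistic included in the count (so p ≥ 1/(n_perm + 1)).
Significance uses a strict inequality, so an exactly-null map yields no
discoveries.  When 2^R ≤ n_perm (R = repetitions per label) all swap
patterns are enumerated and the test is exact.

Discreteness caveat: complementary swap patterns negate the Mem map, so the
2^R patterns collapse to 2^(R−1) distinct values of the max statistic.
With R = 4 the attainable rejection levels are multiples of 1/8, and the
realized family-wise error rate closest to a nominal α = 0.1 is
1/8 = 0.125.  The Monte-Carlo null calibration in the acceptance script
estimates exactly this quantity; more repetitions per label refine the
granularity.

## Synthetic generator

The generator emulates the *structure* of the study inputs, not their
statistics: sinusoidal temperature and short-wave radiation seasonal cycles
(phase flipped south of the equator) with AR(1) weather noise and smoothly
spatially varying amplitudes; precipitation as a seasonally modulated pulse
process (Bernoulli occurrence × exponential magnitude, nonnegative by
construction); relative humidity loosely anti-coupled to temperature; and
smooth random static fields in [0, 1] for soil and land-cover properties.
Defaults (12 × 12 pixels, 8 years, τ = 4 steps ≈ 2 months of soil-water
persistence, observation noise SD 0.02 on a [0, 1] proxy) are chosen as a
small but ecologically plausible configuration; τ = 4 corresponds to the
multi-week soil-moisture persistence that motivates memory effects in
water-limited regions.

The vegetation proxy responds to a leaky store
`S_t = (1 − 1/τ)·S_{t−1} + P_t` (clipped at a capacity) through a
saturating Michaelis-type response `V = V_max·S/(S + K)` times a smooth
temperature limitation, plus Gaussian noise, clipped to [0, 1] — mimicking
greenness saturation at high vegetation density.  The ground-truth memory
length is the smallest k with `(1 − 1/τ)^k ≤ 0.05` (τ = 1 has none: the
store is current precipitation only).  The latent store is returned for
diagnostics but never exposed to models.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic NDVI noise structure and observation
gaps, fire and land-use disturbance, nutrient limitation, snow dynamics,
topographic heterogeneity, or the spatial covariance of real reanalysis
fields.  Tests on synthetic cubes establish that the machinery recovers a
*known, planted* memory structure; they say nothing about effect sizes in
real observations.

## Scaled-down experiment sizes

The planted-memory recovery experiment in the test suite uses a 12 × 12
grid over 9 years with 2 temporal folds of 5 years (9 years is the smallest
span admitting an integer fold plan with a 1-year warmup overlap), spatial
blocks of 3, one repetition, and the model family n ∈ {full, 0, 1, 2, 3}
with the small-model defaults above; τ = 1.25 gives a true memory length of
2 steps.  The null-calibration experiment uses a 10 × 10 grid, 48 steps,
4 repetitions per label and 999 requested permutations (the exact test
enumerates 16 patterns), with thousands of simulated datasets in the
acceptance script.  These sizes were chosen so each experiment completes in
minutes on one CPU while the planted effects remain well separated from
noise.

## Numerical conventions and edge cases

- Aggregation/filter thresholds: "more than" is strict; equality keeps.
- Standardization raises on zero-variance predictors, naming the variable.
- Regional error summaries use the population (not sample) standard
  deviation across pixels.
- Months on the 24-step calendar are 2 consecutive steps; monthly summaries
  pool both steps across years, on biome-aggregated series.
- Climate-space bins are half-open on the right; cells with fewer than 10
  member pixels are reported but masked.
- The month-wise across-year skill comparison needs ≥ 2 years; biome ×
  hemisphere cells with fewer than 10 pixels are suppressed.
- All randomness flows from explicit seeds (`numpy.random.Generator`);
  plans, schemes, training and the permutation test are reproducible
  bit-for-bit for a fixed seed on a fixed platform.

## Known limitations

- The no-leakage guarantee of standardization applies to the mean/variance
  transform; biome areas and retention masks are computed once on the full
  record.
- The LSTM implementation favours clarity over speed; it is adequate for
  the desk-scale problems here, not for continental multi-decade records.
- Temporal folds with zero overlap disable the warmup mechanism; the first
  steps of each span are then evaluated from a cold state.
- The memory bound is exact at training time only (see above); with very
  long prediction sequences M_n models may express longer dependencies
  than n steps if such mappings were learnable from n-step evidence.
- Hyper-parameter search is out of scope; the defaults above are fixed.
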