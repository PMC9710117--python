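# Methods

## Model

The spatial random forest (SRF) is a two-stage regression forest for areal
data. Stage one fits an ordinary random forest RF_1 on the covariates. Stage
two computes, for every region i, the neighbourhood-averaged first-stage
residual

    r_i = (1 / n_i) * sum_{j ~ i} (y_j - yhat_j),

where j ~ i is the symmetric contiguity relation, n_i the number of
neighbours of i, and yhat_j the stage-one prediction for region j; the
region's own residual is excluded because the relation excludes self. RF_2 is
then fit on the covariates plus the single extra column r. The construction
assumes that whatever spatial structure the covariates miss is locally
smooth, so that the average residual of a region's neighbours is informative
about its own error — the same locality assumption behind conditional
autoregressive models. One augmentation pass is performed; the procedure is
not iterated to convergence.

**Out-of-bag residuals.** yhat_j in stage one is the out-of-bag (OOB)
prediction: the average over trees whose bootstrap sample excluded j. In-bag
forest residuals are shrunken toward zero by construction (trees interpolate
the samples they saw), which would make r nearly vacuous and leak the
response into a covariate. An `in_bag` mode exists for sensitivity analysis.
Prediction for unseen regions is transductive: r is the mean stored OOB
residual over the region's *training* neighbours, 0 when it has none (or when
the region is an island). Using the stored OOB residuals at test time keeps r
on the same scale RF_2 was trained on.

**Geographical random forest (GRF).** The comparison baseline fits one local
forest per training region on its `bandwidth` nearest training regions
(Euclidean centroid distance, self included, distance ties broken by region
order), and predicts an unseen region with the local forest of its nearest
training region. There is no distance-weighted blending: nearest-local-model
prediction is the simplest rule consistent with a disaggregation into local
sub-models and is exactly testable. Local neighbourhood members are re-sorted
into original training order before fitting, so a bandwidth covering the
whole sample reproduces the global forest bit-for-bit at the same seed — a
useful exact degenerate check.

## Autocorrelation statistics

Moran's I = (n / S0) Σ_ij w_ij z_i z_j / Σ_i z_i² and Geary's
C = (n−1) Σ_ij w_ij (v_i − v_j)² / (2 S0 Σ_i z_i²) are computed over the
contiguity weights. **Binary weights are the default**: they make the
closed-form anchors exact (the 2×2 checkerboard has I = −1, the perfect
dissimilarity clustering value, and C = 1.5) and match the intuition of
counting discordant contiguous pairs; row-standardized weights are available
by flag. Inference is by random relabelling of the values across regions
(default 999 permutations) rather than the normal approximation — valid at
small n and free of distributional assumptions. P-values use the
(1 + #extreme) / (B + 1) convention; the two-sided p doubles the smaller
tail, capped at 1. Reported residual diagnostics are two-sided by default.

Tango's index C(λ) = (r − p)ᵀ A(λ) (r − p), with r the case shares, p the
population shares and A(λ)_ij = exp(−4 d_ij² / λ²), measures global
clustering of counts at spatial scale λ. The maximized excess events test
scans a λ grid (default: quartiles of the inter-centroid distances) and
corrects for that scanning by the min-p Monte-Carlo method: replicate counts
are drawn multinomially with probabilities p, each replicate's per-λ p-values
are computed by ranking within the replicate set, and the reported p-value is
the share of replicates whose minimum per-λ p-value is at least as small as
the observed minimum. Distances are Euclidean on the supplied coordinates;
longitude/latitude at continental scale should be projected first (documented,
not enforced). Positive-definiteness of A(λ) is not required by the test as
implemented, only checked empirically through the nonnegativity of C(λ) on
the inputs exercised.

The empirical semivariogram bins region pairs by centroid distance into
equal-width bins on (0, max_dist] and reports
γ(bin) = Σ (v_i − v_j)² / (2 · count); empty bins carry NaN.

## Imputation and splitting

Missing continuous values are filled with the mean of the neighbours'
originally observed values; missing categorical values with the modal
neighbourhood category, ties broken lexicographically so the result is
deterministic. Only pre-imputation values feed the fill (single pass): this
is order-independent and makes the operation idempotent. A region with a
missing value that no neighbour observes — an island in particular — cannot
be filled and is dropped and reported, mirroring how offshore regions without
contiguous neighbours must be excluded in practice. The train–test split
assigns floor(train_frac · n) regions to training by seeded sampling without
replacement; a fraction whose train or test share rounds below one region is
rejected as an empty partition.

## Evaluation protocol

RMSE and R² follow their textbook forms; R² uses the scored sample's own mean
in the denominator, so it can be negative on held-out data. Node impurity is
the within-node population variance (divisor N). Impurity importance routes
the scored sample down every tree and credits each split with the
size-weighted impurity decrease (n_t·δ(t) − n_l·δ(l) − n_r·δ(r)) / N — this
from-scratch traversal is what makes *test-based* impurity importance
possible; on a bootstrap-free tree evaluated on its training data it
reproduces the classical mean decrease in impurity exactly. iMSE is the mean
increase in test MSE over 10 permutations of the covariate column (delegated
to scikit-learn's permutation importance with an MSE scorer). Shares clip
negative iMSE values at zero before normalizing; if no covariate shows any
effect the shares degrade to uniform. Cross-validation partitions regions
into k seeded random folds (spatially blocked CV is out of scope), refits the
model per fold with neighbourhoods restricted to the fold's training
subgraph, and scores pooled out-of-fold predictions.

## Synthetic data

The generator emulates the target setting — a lattice of contiguous regions
with covariate effects plus a spatially autocorrelated error field — via a
simultaneous autoregressive (SAR) process: u = (I − ρ W)⁻¹ ε with W the
row-standardized rook matrix and ε i.i.d. N(0, noise_sd²). SAR was chosen
over CAR because it is a single exact sparse solve with an explicit
controllable ρ ∈ [0, 1); ρ = 0 collapses to i.i.d. noise. Covariates are
i.i.d. N(0, 1), spatially unstructured by default so that spatial signal in y
is attributable solely to u (a `smooth_covariates` option filters them
through the same SAR operator for confounded scenarios). The response is
y = Xβ + u, or its logistic transform for strictly-(0,1) proportion-like
outcomes. Defaults — 15×15 lattice, ρ = 0.7, β = (1.0, 0.5), noise_sd = 1 —
put covariate signal and spatial field on comparable variance scales, the
regime where ignoring space visibly hurts but the covariates still matter.

What the generator does **not** emulate: irregular region geometries and
degree distributions, heteroscedastic sampling noise from varying cohort
sizes, covariate collinearity, and measurement error. Tests passing on these
synthetics therefore demonstrate the mechanics and the qualitative ordering
of the methods, not their performance guarantees on any particular survey.

## Numerical and design choices

- Forest defaults: 500 trees, unlimited depth, min_leaf = 5,
  mtry = ceil(p/3) — conventional regression-forest settings.
- `max_depth = 0` requests a stump forest realised as a bootstrap-free
  single-leaf tree: every prediction is exactly the training mean, giving a
  deterministic oracle for composition tests.
- OOB predictions regenerate each tree's bootstrap draw from its stored seed;
  a region present in every bag (rare beyond a few trees) falls back to the
  full-forest prediction, logged and counted.
- RF_2's seed is RF_1's seed + 1: distinct, reproducible streams.
- One global seed expands to per-stage seeds through fixed spawn keys
  (simulate=0, split=1, forest=2, permutation=3, importance=4, cv=5), so
  adding a stage never perturbs earlier stages.
- Island fallbacks (r = 0) and GAL symmetrization are logged, never silent.
- Degenerate inputs (constant fields, perfect fits, empty nodes) raise typed
  errors rather than returning NaN.
- CLI output prints at 6 significant digits; full precision is kept
  internally and in CSV artifacts.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 30 paired replicates of the
15×15 / ρ = 0.7 SAR design with 500-tree forests and 999-permutation Moran
tests for the SRF-vs-RF comparison; 200 seeds × 999 permutations at n = 100
for null calibration; 200 null replicates with 199 Monte-Carlo draws for MEET
type-I error; and 20 replicates at n = 200 for importance recovery. These
sizes give binomial standard errors of 1–3 percentage points on the reported
rates while keeping a full run around a minute on one CPU.

## Known limitations

- The SRF residual covariate is transductive at prediction time: it uses the
  observed responses of training neighbours, so prediction quality degrades
  for regions far (in the graph) from any training region.
- Residual Moran p-values are not adjusted for the estimation of the model
  that produced the residuals; they are a diagnostic, not a formal test of
  model correctness.
- GRF retrains one forest per region and scales linearly in n_train; no
  bandwidth auto-tuning beyond grid search by CV is provided.
- Contiguity must be supplied; the package does not derive it from polygon
  geometry.
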