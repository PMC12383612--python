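# Methods note

This note records the mathematical model, the default parameter choices and
their rationale, the scope of the synthetic data generator, and the
numerical decisions made in the implementation.

## 1. The presence-background maximum-entropy model

### Estimation problem

Let the landscape be a finite set of cells with environmental predictor
vectors, and let `f(x) ∈ R^d` be a vector of feature transformations of the
predictors at cell `x`. Given `m` presence cells `x_1..x_m` and a background
sample of `N` cells, the model is the Gibbs distribution

    q_λ(x) = exp(λ · f(x)) / Z_λ,    Z_λ = Σ_{x ∈ background} exp(λ · f(x)),

and `λ` maximises the L1-penalised average presence log-likelihood

    J(λ) = (1/m) Σ_i λ · f(x_i) − log Z_λ − Σ_j c_j |λ_j|,

with per-feature penalties `c_j = RM · β_j` (see §3). `J` is concave, so the
optimum is unique up to flat directions and independent of initialisation.
This is the dual of the maximum-entropy problem: among distributions whose
feature means are within `c_j` of the presence sample means, `q_λ` is the
one with maximum entropy (closest to uniform on the background).

Assumptions inherited from the presence-background formulation:

- presences are an unbiased sample from the species' occupancy distribution
  (no survey bias is modelled; thinning mitigates only duplicate/clustered
  records at the grid resolution);
- the background sample represents the available environment;
- predictors measured at cell centres are representative of the cell.

### Feature classes

Each predictor is min-max scaled to `[0, 1]` using the background minimum
and maximum, so penalties are comparable across variables. On the scaled
value `s`:

- **L** (linear): `s`;
- **Q** (quadratic): `s²`;
- **P** (product): `s_a · s_b` for every unordered pair of variables;
- **H** (hinge): forward `max(0, (s − k)/(1 − k))` and reverse
  `max(0, (k − s)/k)` at `K` evenly spaced interior knots `k = i/(K+1)`;
- **T** (threshold): `1[s > k]` at the same interior knot positions.

Features are ordered deterministically (class L, Q, P, H, T; then variable
order; then knot order), so coordinate descent visits coordinates in a fixed
sequence and results are exactly reproducible. A predictor that is constant
over the background contributes only an identically-zero linear feature: it
carries no information and any nonlinear transform of it would be constant.

### Outputs

With `H = −Σ q log q` the entropy of the fitted distribution over the
background and `η(x) = λ·f(x)`:

- **raw**: `q(x)` renormalised over the prediction domain (sums to 1);
- **logistic**: `q e^H / (1 + q e^H)` computed with the *training* `log Z`
  and `H`; calibrated so the uniform model scores 0.5 — an interpretation
  as suitability under an assumed 0.5 prevalence;
- **cumulative**: percentage of total raw mass on cells with raw value ≤
  the cell's own value.

When projecting onto new layers (e.g., future scenarios), **clamping**
optionally truncates each predictor to its training `[min, max]` before
feature evaluation, preventing uncontrolled extrapolation of open-ended
features.

### Model interpretation

- **Regularized training gain**: `J(λ̂) − J(0)`, the penalised improvement
  of the mean presence log-probability over the uniform model (0 for the
  uniform model, ≥ 0 at the optimum).
- **Percent contribution**: during fitting, each accepted coordinate step's
  objective improvement is credited to the variable owning the feature
  (product features split the credit equally between their two parents);
  credits are normalised to percentages. This is path-dependent in general
  but deterministic here because the coordinate order is fixed.
- **Jackknife**: refits with only / without each variable to report
  standalone and unique training gains.
- **Response curves**: the marginal effect of one variable with all others
  held at their background means; the "optimal range" is the interval where
  the logistic response exceeds a threshold (linear interpolation at the
  crossings).

## 2. Model selection

Candidates are the cross product of feature combinations
(`L, H, LQ, LQH, LQHP, LQHPT, QHP, QHPT, HPT`) and regularization
multipliers (`0.5 … 4.0` in steps of `0.5`). Per candidate:

- **AICc** `= 2k − 2L + 2k(k+1)/(m−k−1)` with `k` the number of non-zero
  coefficients and `L` the *unpenalised* presence log-likelihood of the
  model fitted on all presences; undefined (excluded) when `m − k − 1 ≤ 0`.
- **OR10**: the threshold is the `ceil(0.1·n_train)`-th smallest training
  presence score; the rate is the fraction of test presences strictly below
  it, averaged over partition folds.
- **AUC.diff**: training AUC minus test AUC (Mann–Whitney estimator with
  half-credit for ties; presence vs background scores).

The selected model minimises ΔAICc (so the minimum is exactly 0 by
construction), with ties broken by lower OR10, then lower AUC.diff, then
fewer parameters. Final models are fitted as `n_rep` replicates on random
75/25 presence splits; the reported suitability layer is the mean of the
replicate logistic layers, and training/test AUC are summarised as
mean ± sd with a conventional five-level accuracy banding of the mean.

## 3. Default parameters and why

| Parameter | Default | Rationale |
| --- | --- | --- |
| hinge / threshold knots | 30 | enough resolution for smooth responses; more knots only add near-duplicate features that L1 zeroes out |
| background sample | 10,000 | standard size at which background means stabilise; sampling is seeded and mask-aware |
| β schedules | L/Q: (10,1.0)(30,0.2)(100,0.05); P: (10,2.6)(30,1.0)(100,0.25); H: 0.5; T: (10,2.0)(100,1.0), linearly interpolated in m | tighter penalties for small samples and for feature classes with many members; the per-feature penalty is `β·max(sd_bg(f_j),10⁻⁶)/√m`, scaling like a standard error of the feature mean |
| RM grid | 0.5–4.0 step 0.5 | brackets the unit multiplier on both sides; finer steps rarely change the AICc winner |
| classification breaks | 0.1 / 0.3 / 0.5 | conventional non/low/medium/high logistic bins |
| binary threshold | 0.1 | "any suitability" presence/absence cut; rates are reported over the union of ever-suitable cells so stability+contraction+expansion = 100% |
| centroid weighting | logistic × cell area over cells ≥ threshold | cell areas shrink with latitude on a geographic grid; ignoring them biases centroids equatorward |
| years between periods | 20 | mid-decade spacing of the 2050s/2070s/2090s convention; velocity = displacement/20 |
| collinearity threshold | \|ρ\| > 0.75 (Spearman) | standard SDM screening cut; of each violating pair the variable with lower preliminary-model contribution is dropped, largest correlations resolved first |
| solver tolerance | 10⁻⁶ on the KKT violation | coefficient changes below this do not move any reported quantity at the precision reported |

## 4. Synthetic data: scope and limits

The generator produces spatially autocorrelated layers (Gaussian-smoothed
white noise, rescaled to plausible ranges), a known ground-truth suitability
surface (softmax of a linear or quadratic form in the scaled layers), and
clustered occurrence samples (cluster centres drawn ∝ truth, members
jittered around them). Future scenarios add a poleward drift to every layer
proportional to forcing strength and period.

This supports exactly what the package needs: end-to-end execution,
parameter-recovery experiments against a known truth, and qualitative
range-shift signal (poleward centroid movement increasing with forcing).
It does **not** emulate real climate fields: layers are independent of one
another (no realistic cross-correlations), the drift is a caricature of
warming, there is no survey bias, and the default 60×90-cell domain is far
smaller than a national-scale study. Quantities computed on synthetic runs
characterise the *software*, not any real species.

## 5. Numerical choices

- **Solver**: cyclic coordinate descent. Each coordinate takes a Newton
  step on the smooth part, soft-thresholded by the L1 penalty, then a
  halving line search (≤ 40 steps) accepts only strict objective
  improvement — the objective is monotone and fitting cannot diverge. The
  linear predictor `η` and `log Z` are maintained incrementally;
  convergence is declared when the maximum KKT violation falls below the
  tolerance, with a stall guard for negligible cycle improvement.
- **Overflow safety**: all partition functions use `logsumexp`; logistic
  and cumulative outputs are computed in log space where possible.
- **Cell areas**: exact spherical zone formula
  `R²·Δλ·(sin φ_top − sin φ_bottom)` with `R = 6371.0088 km`; distances use
  the haversine formula, bearings the standard `atan2` great-circle form.
- **Determinism**: all randomness flows from explicit seeds through
  `numpy.random.default_rng`; the pipeline derives per-stage seeds from the
  master seed with a fixed hash, so re-running a config reproduces every
  output byte-for-byte.
- **Raster I/O**: ESRI ASCII grids (plain text, `NODATA_value -9999`) —
  human-diffable and dependency-free; vector tracks are GeoJSON.
- **Ties**: deterministic everywhere — thinning breaks equal distances by
  smallest record id; screening breaks equal contributions lexicographically;
  selection breaks equal ΔAICc by OR10, AUC.diff, then parameter count.
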