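# Methods

`sdml` implements a small-data machine-learning workflow for predicting the
log10 root concentration factor (log RCF) of per- and polyfluoroalkyl
substances (PFASs) in hydroponically grown plants from molecular descriptors
(molecular weight MW in g/mol, log Kow, pKa, TPSA in Å²), exposure covariates
(exposure time in days, a plant-species code) — preprocessing, composite
feature selection, stratified SMOTER+VAE data augmentation, boosted-tree
modeling with Bayesian tuning, tiered Shapley explanation, and three
symbolic-regression engines. This note records the model assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic study conditions

The workflow is exercised end to end on simulated exposure tables
(`sdml.synthdata`), because a curated literature dataset of this kind is not
generally redistributable. The generator draws MW uniformly on [214, 714]
g/mol (short- to long-chain PFAS masses — a plausibility choice carrying no
chemical claims), log Kow positively correlated with MW
(slope 1 per 100 g/mol, Gaussian scatter 0.6), pKa on [-1, 5], TPSA on
[0, 80] Å², exposure time on [1, 60] days, and a species code with
per-species target offsets spanning 3 log units, which makes the log RCF
marginal multi-modal. The planted response is

```
logRCF = b1·(MW/100) + b2·(1 − e^(−0.005·t)) − b3·WSI
         + b4·(MW/100)·(1 − e^(−0.005·t)) + offset(species) + N(0, σ²)
```

with `WSI = TPSA / (MW·(1 + 0.5·logKow))` (the water-solubility index),
defaults `b = (1.0, 0.8, 1.2, 0.5)` and `σ = 0.4`. The defaults put the
attainable test R² near 0.96; tree models at n_train = 150 reach ≈ 0.93.

What the generator does *not* emulate: real inter-descriptor correlation
structure beyond the MW–logKow link, heterogeneous measurement error across
literature sources, non-equidistant species effects (the default offsets are
linear in the species code, so linear models capture them exactly), and any
chemistry beyond the planted formula. Passing tests therefore demonstrate
that each algorithm recovers structure it is designed to recover — not that
the workflow generalizes to any particular experimental dataset.

## Preprocessing

Order is fixed: impute → trim → transform → encode.

* **Imputation** is round-robin random-forest regression (each incomplete
  column regressed on all others, iterated), backed by sklearn's iterative
  imputer with a 100-tree forest, tolerance 1e-3, at most 10 rounds.
  Deterministic for a fixed seed.
* **Outlier trimming** removes rows whose *target* lies outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; quartiles use linear (type-7) interpolation,
  the most common convention, stated for reproducibility. Feature outliers
  are left to the tree models. Re-trimming after removal can remove more
  rows (the fences shrink); trimming is only idempotent when nothing was
  removed.
* **Skew transform**: continuous columns with adjusted Fisher–Pearson sample
  skewness > 1 are replaced by log10(x + shift), shift = max(0, 1e-6 − min x),
  since RCF-style quantities are log10-reported.
* **Encoding**: categorical labels map to integer codes in order of first
  appearance; tree models split on ordinal codes natively (one-hot is a
  config option).

## Composite feature score

Five statistics are computed per feature against the target: the univariate
F statistic, k-NN mutual information (k = 3), distance correlation, an
equi-partition MIC approximation with grid budget B = n^0.6, and regression
ReliefF (k = 10 neighbors, range-scaled differences). Each is min–max
normalized across features and combined with weights (default equal, 0.2
each). Stability is the fraction of bootstrap resamples (default 100 at 80%
size) in which the feature ranks in the top half of the combined score. The
final composite is

```
composite = combined · stability · 1 / (1 + max(0, VIF − 10)/10)
```

which stays in [0, 1]; VIF = 10 is the classical multicollinearity
threshold, and the multiplicative form means an exactly duplicated feature
drives both copies toward zero. A deliberate consequence: monotone
transforms of one strong descriptor (MW, MW², √MW …) share their signal and
are *all* penalized, so the ranking favors non-redundant drivers. Constant
features are flagged and scored zero; ties in selection break by name for
determinism.

## Stratified augmentation

* **Binning**: `n_bins = max(6, min(12, floor(n_train/12)))` (floor keeps the
  count integral; the bounds make the choice inert near them). Strategy is
  equal-frequency when |skewness| > 1, else equal-width, so skewed targets
  keep balanced bin counts while symmetric ones keep interpretable intervals.
  Binning requires ≥ 24 rows (2 per bin at the minimum count).
* **Quotas**: the synthetic total T = round((factor − 1)·n_train) is
  apportioned over bins by largest remainder with weights deficit+1, deficit
  being the gap to the fullest bin — sparse target regions get the most new
  samples, and quotas sum exactly to T. "Expanded nine times" is read as
  final size = 9 × n_train (462 → 4158 rows).
* **SMOTER**: `x_new = x_i + μ(x_nn − x_i) + δ`, μ ~ U(0,1), with the seed
  row drawn uniformly in a bin and the neighbor among its k = 5 nearest
  same-bin rows under a standardized Euclidean metric on continuous
  features. Mixed data follows the nominal-SMOTE convention: when the bin
  holds another row with the seed's categorical profile, candidates are
  restricted to that profile, so interpolation does not blend across species
  (which would inject target noise of the size of the species offsets).
  δ is per-feature Gaussian with scale 0.02 standard deviation; the target
  interpolates with the same μ. Every draw (seed, neighbor, μ, δ) is logged
  so a replay oracle can verify each synthetic row coordinate-wise.
* **VAE**: a tanh MLP (hidden 32-16, latent 8) over the standardized
  continuous features, categorical codes and target jointly, trained 200
  epochs with Adam (2e-3) on squared reconstruction error + KL to the
  standard-normal prior (weight 1). It is implemented directly in numpy with
  manual gradients — the network is small enough that no autodiff framework
  is warranted — and the whole state serializes to a dict. Decoded samples
  de-standardize, snap categorical columns to the nearest observed code, and
  join the bin containing their decoded target; decoded targets outside the
  observed range ± 5% are rejected and resampled.
* **Quality control**: a candidate is credited against a quota only if its
  continuous features lie within its bin's observed envelope ± 5% of the
  per-bin range and its target within the bin edges ± 10% of the bin width.
  Generation rounds alternate SMOTER (share 0.5) and VAE batches; after half
  of the 20-round budget, SMOTER fills any remainder for donor-rich bins.
  Unmet quotas after the budget yield a warning and a partial augmentation,
  never an exception. Bins with fewer than two donors route their quota to
  the VAE.

## Models and tuning

Four regressors: `lightgbm_like` and `xgboost_like` wrap the corresponding
boosters; `catboost_like` is an ordered gradient-boosting stand-in built on
sklearn's GradientBoostingRegressor; `random_forest` is the bagging
baseline. Search spaces use log-uniform scales for learning rates
([1e-3, 0.3]) and regularization, uniform scales for subsampling fractions
([0.5, 1]), integer ranges for depth/leaves, and conditional branches (the
LightGBM bagging fraction is sampled only when bagging is enabled) so
invalid combinations never arise.

The tuner is a univariate tree-structured Parzen estimator: after a 10-trial
random start-up, trials split at the γ = 0.25 quantile into good/bad sets,
numeric parameters get a Parzen density per set in the transformed space,
and candidates drawn from the good density are ranked by the density ratio.
Each trial's randomness derives from (seed, trial index), so a longer budget
replays a shorter one exactly and the incumbent CV RMSE is non-increasing in
budget. The objective is mean 5-fold CV RMSE; the winner refits on the full
training table; the test set is scored exactly once per report; augmentation
is applied to training data only. Percent improvement is
(old − new)/old × 100.

## Explanation tiers

1. **native** — the booster's own contribution output (XGBoost
   `pred_contribs`, LightGBM `pred_contrib`); exact up to the booster's
   float32 arithmetic.
2. **tree** — the package's path-dependent Tree SHAP for sklearn tree
   ensembles: the polynomial-time extend/unwind traversal with expectations
   from each node's training cover. Additivity holds to ~1e-12 and a feature
   absent from every split receives exactly zero.
3. **kernel** — model-agnostic weighted regression under the Shapley kernel
   against a k-means background (10 centers weighted by cluster size);
   coalitions are enumerated exhaustively when 2^M − 2 fits the 2M + 2048
   sample budget, making the estimate exact up to the background
   approximation, and the efficiency constraint is imposed algebraically so
   additivity holds by construction.

Cross-model importance is mean |SHAP| per feature normalized to sum 1,
aggregated by mean rank.

## Symbolic regression

Equations are sums of coefficient × product-of-primitive-factors (a factor
is a transform of one feature raised to a power, transforms: identity,
sqrt|x|, ln(|x|+1e-6), e^(−0.005x), sin, |x|), plus an intercept; evolved
expressions that do not flatten into that grammar carry their protected
expression tree instead. Both forms round-trip through JSON to identical
evaluators, and all operators are protected (ε-floored logs and divisions)
so finite inputs give finite predictions. The two published evolved
equations ship as demo fixtures under a documented parse (base-10 log of the
absolute-protected argument; exponents bind to the preceding variable)
because their typeset form is ambiguous; they are format illustrations, not
reference values.

* **GP**: population 2000, 100 generations by default; tournament 20;
  crossover/mutation/reproduction 0.7/0.2/0.1 with one elite; fitness =
  RMSE + 0.001 × tree size; ramped initialization; 64-node cap. The power
  primitive is realized as unary square/cube rather than a binary exponent,
  keeping every evolved expression finite.
* **MFTEC** (select-then-construct): stage 1 keeps the top-m (default 8)
  features by composite score; stage 2 builds linear, pairwise-interaction,
  and transform blocks (sqrt, ln, squares, plus e^(−0.005x) for time-like
  features); stage 3 fits an elastic net per block on standardized columns
  and combines block predictions with non-negative least squares (a ± ones
  column pair realizes a free intercept). The stack flattens algebraically
  into one equation whose predictions equal the pipeline's to float
  precision.
* **HSIE** (construct-then-select): all monomials to order 3 plus sqrt/ln
  transforms, protected pairwise ratios, and — because uptake kinetics are
  first-order in time — the e^(−0.005t) decay of time-like features and its
  pairwise interactions. Logs and ratio denominators are admitted only for
  columns bounded away from zero (min |x| > 0.05·sd), since a protected
  operator evaluated near its floor turns into a spike on unseen rows.
  Columns are standardized; an L1 path with 5-fold CV and the
  one-standard-error rule picks the support; an unpenalized least-squares
  refit on the raw columns yields coefficients on the original scale, with
  numerically-zero refit coefficients pruned and one final refit. A hard cap
  of 20 000 dictionary columns guards against runaway feature sets. With
  max_order = 1 the dictionary is the plain features and the result is OLS.

## Benchmarks and problem sizes

The directional benchmarks (`sdml.benchmark`) use 20 replicates at
n_train = 150 / n_test = 200 with the generator defaults, default model
hyperparameters, and a reduced GP budget (population 200, 15 generations);
the selection-recovery suite uses 160 rows, 20 features and 25 bootstrap
resamples; these sizes keep a full run in the minutes range on one CPU while
leaving the directional signals resolved. The equation engines see the raw
descriptors only and must discover composite structure themselves.

Findings the test suite computes on these conditions: augmentation leaves
the mean test R² of the three boosting models unchanged or slightly
improved; both sparse equation engines sit essentially at the noise ceiling,
with the select-then-construct stack a hair above the construct-then-select
engine — under a planted truth that lies inside MFTEC's predetermined
transform span, shrinkage beats the relaxed refit by estimation variance,
so the dictionary-richness advantage that HSIE shows on complex real data
has nothing to bite on here. Equations fitted on augmented rather than
original data lose a little accuracy for the same reason: at the ceiling,
synthetic rows only add noise. These are properties of the synthetic
conditions, documented rather than hidden.

A related degeneracy: on noiseless data the HSIE dictionary contains
near-collinear surrogates (e.g. ln MW for the kinetics term over a narrow
range), so the L1 path occasionally selects an equivalent support with
indistinguishable fit; exact support recovery is therefore asserted in most,
not all, seeds.

## Numerical conventions

Split sizes use half-up rounding. Missing values are NaN; CSV I/O writes 17
significant digits and parses with round-trip precision so load(write(x))
is exact. All stage randomness flows from explicit integer seeds through
`numpy.random.default_rng`; boosters run single-threaded by default so
end-to-end runs are bit-reproducible. Selection and quota ties break toward
the lexicographically first name / lowest bin index.
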