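# Methods

## The optimization problem

Wrapper feature selection treats subset choice as minimization of

    f(m) = μ · (1 − A_c(m)) + (1 − μ) · d_s(m) / D_t ,    μ = 0.99,

over binary masks `m ∈ {0,1}^{D_t}`, where `A_c` is the cross-validated
accuracy of a fixed classifier on the selected features and `d_s` the subset
size.  With `μ = 0.99` a one-percentage-point accuracy change outweighs any
subset-size change below `0.99·D_t/1 ≈ D_t` features, so the size term acts
as a tie-breaker among equally accurate subsets.  `f` ranges over `[0,1]`;
after empty-mask repair its infimum is `(1−μ)/D_t` at perfect accuracy.

## The wrapper fitness

* **Binarization.**  Positions are clamped to `[0,1]`; feature `j` is
  selected iff `x_j > 0.5` (strict).  An empty mask is repaired by selecting
  the largest coordinate (random coordinate if all are equal), because the
  classifier is undefined on zero features.
* **Classifier.**  5-nearest-neighbour, Euclidean distance, majority vote.
  Tie-breaks are pinned so that every fitness value is bit-reproducible:
  equidistant neighbours are ranked by training index (stable sort), vote
  ties go to the smallest class label.  The test suite checks exact
  agreement with scikit-learn's `KNeighborsClassifier` on random masks.
* **Scaling.**  Features are min-max scaled to `[0,1]` using the training
  portion of each fold, applied to the evaluation portion with the training
  parameters.  Unscaled KNN distances would be dominated by feature units.
  Constant training features scale to zero (range treated as 1).
* **Evaluation modes.**  Pooled stratified 10-fold cross-validation
  (default; folds fall back to unstratified with a warning when a class has
  fewer members than folds) or a single stratified 80/20 holdout.
* **Memoization.**  Fitness is cached by mask bits within an evaluator;
  KNN-CV is the dominant cost and the search revisits masks constantly.
  Per-fold scaled matrices are precomputed once, so one evaluation is a
  masked pairwise-distance computation.

## The search

Population search (defaults: `n = 10` agents, 50 iterations, positions in
`[0,1]`, 3 babysitters, tournament size 2, `peep = 2`):

* **Alpha phase.**  Per foraging agent: tournament-select a guide among the
  `n − bs` current foragers, propose `X_guide + phi·peep` with per-dimension
  `phi ~ U(−1,1)`, clamp, and accept greedily.  Selection probabilities of
  the share form are applied to the transform `max(fit) − fit_i + ε` so
  that lower (better) fitness gets higher probability under minimization.
* **Sleeping-mound bookkeeping.**  Each proposal scores
  `sm = (fit_new − fit_old)/max(|fit_new|,|fit_old|)` (0 when both vanish);
  the forager average `φ` steers the scout phase.
* **Scout phase.**  `X ∓ CF·phi·rand·(X − M)` with scalar `phi ~ U(−1,1)`
  and `rand ~ U(0,1)` per agent (a coherent troop move; per-dimension `phi`
  is a config switch), minus when `φ` improved.  The movement vector's
  printed quotient form cancels position elementwise, so `M` is the
  broadcast of `Σ sm_i`; the sm-weighted centroid variant is available as
  `m_centroid=True`.  `CF = (1 − t/T)^(2t/T)` decays from 1 to 0.
* **Babysitter exchange.**  Every `round(0.6·max_iter)` iterations the `bs`
  worst agents (never the current best) are re-initialized uniformly.
* **Greedy acceptance** everywhere, so the best-so-far history is monotone
  non-increasing by construction.

## The annealed local search

Single-bit-flip neighbourhood, Metropolis acceptance, geometric cooling
with factor 0.93, initial temperature `T₀ = 2·D_t`.  Two consequences of
that (deliberately conventional) `T₀` shaped the implementation:

* `T₀` is orders of magnitude above the objective's `[0,1]` scale, so a
  fresh schedule per call would never leave the accept-everything regime.
  The driver therefore threads **one** cooling schedule through all
  per-iteration SA calls; the stopping temperature defaults to an absolute
  `10⁻¹²` and, inside the driver, the temperature is floored there so the
  late run behaves as first-improvement hill climbing instead of stopping.
* Only a narrow temperature band (around the objective's quantization,
  `~10⁻³` for 100-sample CV) discriminates between competing subsets.  The
  chain length (proposals per temperature, default 25) paces how many
  proposals the walk spends in that band; short chains rush through it and
  measurably reduce how often the search reaches the enumerable optimum.

The annealer is elitist: it returns the best mask ever visited, so an SA
call can never worsen the solution it was given.  Each per-iteration call
is capped at `max_evals = 100` evaluations (dimension-independent); the
final polish after the main loop defaults to 10× that.  No restarts or
reheating.

## Hybrid orchestration

Per iteration the SA refines the **current best agent's** mask (the
neighbourhood-of-the-best reading of the hybrid design); a literal
per-agent gate — BDMO update when at least half of an agent's coordinates
exceed the 0.5 threshold, SA otherwise — is available as
`per_agent_sa_gate=True`.  After the loop, one larger SA polish refines the
global best.  `bdmo_only` skips every SA call.  Complexity is
`O(max_iter · n · D · T_fitness)` with the KNN evaluation `T_fitness`
dominating; SA adds a bounded number of evaluations per iteration.

## Synthetic data

`make_planted` draws informative features as class-conditional unit-variance
Gaussians and noise features as class-independent standard Gaussians,
classes near-balanced.  **`class_sep` is the distance between adjacent class
centroids over the whole informative block** (per-feature shift
`class_sep/√k`): no small sub-subset of the planted features is
individually sufficient, dropping any informative feature costs measurable
accuracy, and the full planted set is the predictable optimum of the
wrapper objective.  A per-feature separation would instead let the size
penalty prune planted features and make recovery ill-defined.  Optional
label noise flips a fraction of labels.  `make_expression_like` generates
the planted structure in log space and exponentiates (`exp(0.35·L + 2)`),
giving positive, log-normal-like intensities at microarray shapes
(e.g. 62 × 2000).

What the generators do **not** emulate: real microarray covariance
structure, batch effects, heavy-tailed measurement noise, correlated or
redundant informative genes.  Passing tests demonstrate correct search
behaviour on separable planted structure, not expected accuracy on real
tissue data.

`exhaustive_oracle` enumerates all `2^D − 1` nonempty masks (refusing
`D > 20`) with the identical evaluator and tie-breaking as the search, so
"search reached the optimum" is an exact fitness comparison.

## Numerical and design choices

* Fitness ties are broken by fewer features, then lexicographically lower
  selected indices — reported subset sizes are deterministic.
* All stochastic draws of one run flow through a single seeded
  `numpy.random.Generator`; repeated runs use consecutive seeds, and every
  reported result is bit-reproducible from its seed.
* Label encoding is first-appearance order; CSV round-trips are exact
  (`%.17g` writing, round-trip float parsing).
* ARFF files may contain only numeric non-class attributes; anything else
  is rejected rather than silently expanded.
* Wilcoxon signed-rank drops zero differences, uses the exact null up to 25
  effective pairs and the continuity-corrected normal approximation above;
  all-zero differences are reported as `p = 1` with a degenerate flag.
  Friedman mean ranks follow the larger-is-better convention (best
  algorithm per run receives rank `k`).

## Study scales

The validation studies are sized for a single CPU: oracle-equivalence uses
10 datasets with 6–12 features (100 samples) × 20 seeded runs; the paired
hybrid-vs-baseline and recovery studies use a 50-feature planted dataset
(5 informative) × 20 seeds; the expression-scale study is a single 62 × 2000
run configured with a larger annealing budget (`max_evals=250` per
iteration, 12 000-evaluation final polish) because pruning from ~1000
initially selected features to ~10² requires on the order of
`2000·ln(D)` bit-flip evaluations.  The acceptance script repeats the same
studies at 10 runs per condition.

## Known limitations

* The wrapper objective's CV accuracy is quantized at `1/n_samples`; on
  small datasets many masks tie and the size penalty alone decides, which
  can select noise features that happen to fix individual fold errors.
* KNN is the only classifier (by design); no filter scores, no alternative
  distance metrics.
* The optimizer is specialized to the binary feature-selection objective;
  it is not a general continuous-benchmark optimizer.
* No missing-value handling beyond rejection, and no dataset downloaders —
  external benchmark suites must be supplied as CSV/ARFF files.
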