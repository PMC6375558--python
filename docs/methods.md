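# Methods

This note documents the statistical model, the algorithms, the synthetic
benchmark, and the numerical choices made in `chrde`. It states what the code
computes and why; quantitative behaviour is established by the test suite and
the acceptance script, not asserted here.

## 1. Model

### 1.1 Accelerated failure time regression on log time

For subject *i* we observe a time `tau_i > 0`, an event indicator
`delta_i` (1 = event, 0 = right-censored) and a covariate row `x_i` with *k*
entries. The model is linear on log time:

    log(tau_i) = beta_0 + x_i . beta + eps_i .

Fitting minimises the mean squared residual on the log scale after the
censored responses have been imputed (below). The intercept `beta_0` is never
penalized; the solver handles it by centering, which is algebraically identical
to re-setting the intercept to the residual mean after every coefficient
update.

### 1.2 Kaplan-Meier mean imputation

Least squares needs a complete response vector. Events contribute
`y_i = log(tau_i)` directly. A censored subject contributes the Kaplan-Meier
weighted mean of the log event times beyond its censoring time:

    y_i = S(tau_i)^{-1} * sum_{t_(r) > tau_i} log(t_(r)) * dS(t_(r)) ,

where `S` is the product-limit estimate on the training data and `dS(t_(r))`
the probability mass it drops at event time `t_(r)`.

Conventions and edge cases:

- Ties between events and censorings at the same time are resolved
  events-first (a subject censored at *t* is still at risk for events at *t*).
- A censored subject with no event time beyond it keeps `y_i = log(tau_i)`.
  The formula has no mass to average in that case; keeping the censoring time
  is the conservative completion.
- When the largest observation is censored the Kaplan-Meier curve does not
  reach zero and the imputed values are shrunk toward smaller log times
  (the unnormalised tail has mass `< S(tau_i)`). This is a property of the
  estimator as defined, preserved deliberately; the test suite asserts the
  conditional-mean property only in the case where the curve reaches zero.
- Imputation is computed on training data only; held-out metrics use observed
  times.

**Assumptions.** Right censoring independent of the event time given
covariates; enough events for a usable product-limit curve (an all-censored
training set degenerates to a flat curve and triggers a warning); positive
observed times.

## 2. Penalties

All penalties enter the solver through one contract: a per-coordinate value
`p(beta_j)` and its derivative with respect to `|beta_j|` ("slope"). The
contract requires `p(0) = 0`, sign symmetry, and a strictly positive slope
everywhere the solver evaluates it.

### 2.1 Complex harmonic pair

    m(beta; a) = sqrt( (2/(a(a+1))) |beta|   + ((1-a)/a)^2 ) - (1-a)/a ,  0 < a < 1
    n(beta; b) = sqrt( (2/(b(b+1))) beta^2   + ((1-b)/b)^2 ) - (1-b)/b ,  0 < b < 1

combined as `P(beta) = gamma * sum m(beta_j) + (1-gamma) * sum n(beta_j)`,
`gamma in [0, 1]`.

Limiting behaviour (verified to tolerance in the tests):

- `a -> 0`: `m -> |beta|` (lasso); `a -> 1`: `m -> sqrt|beta|` (the l1/2
  penalty). `m` is concave increasing in `|beta|` and supplies sparsity. Its
  slope at zero is `1/(1 - a^2)`, finite — unlike the raw l1/2 penalty.
- `b -> 0`: `n -> beta^2` (ridge); `b -> 1`: `n -> |beta|`. `n` is strictly
  convex and supplies the grouping effect (correlated features enter with
  similar coefficients).

The slope of `n` is exactly zero at `beta = 0`, so a pure-`n` mixture
(`gamma = 0`) would have a zero slope at the origin and an undefined gradient
ratio. The combined slope is floored at `1e-12`; with `gamma = 0` this reduces
the solver to "advance the coordinate with the largest loss gradient", the
natural ridge-like behaviour.

### 2.2 Comparators

Lasso (`|beta|`), an l1/2-type penalty (`sqrt(|beta| + eps) - sqrt(eps)` with
`eps = 1e-8`, smoothing the derivative singularity at zero), elastic net
(`alpha |beta| + (1-alpha) beta^2`) and l1/2+l2
(`alpha (sqrt(|beta|+eps)-sqrt(eps)) + (1-alpha) beta^2`). The smoothing
constant makes the slope at zero large (5000) but finite: inactive features
are heavily handicapped relative to active ones, which is what produces the
penalty's characteristic collapse onto few, strong coordinates. The mixing
weight `alpha` defaults to 0.5 and can be chosen from a small grid
(0.2/0.5/0.8) by cross-validated error (`alpha="cv"`).

## 3. Path-seeking solver

The solver grows the coefficient path greedily from `beta = 0`. Each step:

1. `phi_j = (2/h) sum_i x_ij r_i` — negative loss gradient per coordinate
   (`r` the current residual, `h` the sample count);
2. `lam_j = phi_j / slope_j` — gradient ratio;
3. coordinates whose sign conflicts with the ratio (`lam_j beta_j < 0`) are
   corrected first; otherwise the coordinate with the largest `|lam_j|`
   advances in the direction `sign(lam_j)`;
4. the step length is the smallest increment reducing the loss by 1% of its
   current value, solved in closed form (the 1-D restriction of the loss is a
   parabola), capped at the coordinate's 1-D minimiser so the loss never
   increases.

Termination: `max_j |lam_j| < 1e-6`, or no candidate step can reduce the loss
by more than `1e-10`, or `max_steps` is reached (the trace is then flagged
non-converged and a warning is emitted — not an error, since cross-validated
stopping rarely selects the far end of the path).

A sign-violation candidate whose best step is numerically negligible is
treated as noise and the solver falls through to the global best coordinate;
without this, a coordinate sitting exactly at its capped 1-D optimum can trap
the path.

**Complexity.** With the Gram matrix precomputed, each step updates the full
gradient in O(k); a path of *m* steps costs O(k(m + h)) after the O(hk^2) — in
practice O(hk) column-wise — setup. The incrementally updated gradient and
loss are refreshed from scratch every 1024 steps to control floating-point
drift. On the full benchmark design (2200 features, 400 training samples) one
path plus 10-fold cross-validation runs in a few seconds on one CPU.

### 3.1 Cross-validated stopping

The path is re-grown on each of k folds (default 10); held-out squared error
on the imputed log scale is recorded at every step incrementally. Fold curves
are matched by step index (default; matching by path length `nu` is available
and agrees closely in practice), truncated to the shortest fold path, and the
step index minimising the mean curve is selected. Ties go to fewer active
coefficients, then to the lower index. Step-index matching is justified by the
1%-rule: step *s* corresponds to loss level `0.99^s` relative to the start on
every fold, so indices are comparable across folds.

## 4. Memetic differential evolution over (a, b, gamma)

The chromosome is intron + exon: the intron is the CHR hyperparameter triple,
the exon the coefficient vector fitted under it. Evolution touches only the
intron; each evaluation re-derives the exon by local learning (path fit +
CV stopping on an internal 80% fit split) and scores it on the internal 20%
validation split:

    fitness_i = w_M * (1 - MSE_i / sum_pop MSE) + w_C * CI_i ,

`w_M = 0.95`, `w_C = 0.05`; MSE on the log scale (see §6), CI Harrell's
concordance with ties counted 1/2. Fitness is computed with the population MSE
sum current at evaluation time and stored; stored values are not re-normalised
afterwards, which keeps the greedy `>=` replacement rule and the
monotone-best-fitness invariant exact.

Operators, with reference defaults (population 4, F = 0.9, crossover rate 0.9,
budget 10,000 evaluations, bounds a, b in [0.01, 0.99], gamma in [0, 1]):

- mutation: DE/rand/1, `child = pop_r + F (pop_s - pop_t)` with r, s, t
  distinct from each other and the target; out-of-bounds coordinates are
  reflected back into the box;
- crossover: binomial with a forced component, guaranteeing at least one
  mutant coordinate;
- selection: trial replaces target iff its fitness is `>=` — the population
  never deteriorates;
- local search: simplex crossover around the population centroid. The
  population is expanded about its mean by `w_L = 1` (identity at that
  setting), a candidate is built by the recursive combination
  `C_j = r_{j-1}(tmp_{j-1} - tmp_j + C_{j-1})` with weights
  `r_j = u^(1/(j+1))`, and accepted per slot only when inside bounds and not
  worse in fitness.

The best intron is refit on the complete training data for the final
coefficient vector.

## 5. Synthetic benchmark

### 5.1 Generator

200 key factors (KFs) drawn i.i.d. N(0,1), each regulating 10 genes via the
conditional normal `gene | KF ~ N(rho * KF, 1 - rho^2)` — the standard
hub-and-spokes expression design: genes keep unit marginal variance and
`corr(gene, KF) = rho` exactly, at every `rho`. (A deterministic-mixture
variant `gene = rho KF + (1-rho) z`, with correlation
`rho / sqrt(rho^2 + (1-rho)^2)` and shrinking marginal variance, is available
as `correlation="mixing"`; under it the genes carry almost no independent
signal at high `rho`, which qualitatively changes selection behaviour.)

The first four groups are relevant: coefficient `c` on the KF and `c/sqrt(10)`
on each of its genes, `c in (2, -2, 4, -4)` — 44 relevant variables out of
2200. Log survival time is `Y = X beta_true + eps`, `eps ~ N(0,1)`; observed
times are `exp(min(Y, Y_c))` with log-normal censoring times whose location is
set to the empirical `(1 - censor_rate)` quantile of `Y - z_c`, hitting the
target censoring fraction (default 30%) exactly on each draw.

**Realism and limits.** The design captures the two features that matter for
grouped selection — hub-correlated blocks and group-structured coefficients —
but is idealised: Gaussian expression values, independent groups, homoscedastic
log-normal survival, and a signal-to-noise ratio far above typical microarray
cohorts (signal variance grows as `c^2 (1 + sqrt(10) rho)^2` per group).
Absolute error metrics from this generator do not transfer to real data;
selection *orderings* between penalties are the quantity of interest.

### 5.2 Scoring and harness

A feature is selected when `|beta_j| > 1e-8` (the path moves coordinates by
discrete increments, so exact zeros are meaningful; the threshold only guards
float dust). Sensitivity = selected relevant / 44; specificity = rejected null
/ 2156. The harness draws a fresh dataset and a fresh 2/3 train / 1/3 test
split per replicate from a spawned seed sequence, runs each registered method,
and aggregates means with standard errors. Replicate failures are recorded and
skipped, not fatal.

## 6. Metric scale

Validation MSE (DE fitness, CV curves, benchmark tables) is computed on the
log-time scale: `mean((log tau - linear predictor)^2)`. Squared error on the
raw time scale is available (`metric_scale="time"`, with the linear predictor
clipped at ±500 before exponentiation to guard overflow) but is dominated by
a handful of large times whenever the log-scale response has variance in the
hundreds, as it does under this generator at high correlation — the clipped
exponential makes it a diagnostics-only metric here. Concordance is computed
from the linear predictor and is scale-invariant.

## 7. Parameters (defaults)

| Parameter | Default | Where |
| --- | --- | --- |
| CHR a, b, gamma (no optimizer) | 0.5, 0.5, 0.5 | `model.DEFAULT_CHR` |
| comparator mixing alpha | 0.5 (grid 0.2/0.5/0.8 via `"cv"`) | `model.ALPHA_GRID` |
| step fraction | 0.01 | `path.STEP_FRACTION` |
| lambda tolerance | 1e-6 | `path.LAMBDA_TOL` |
| loss tolerance | 1e-10 | `path.LOSS_TOL` |
| max path steps | max(10k, 1000); 4000 in benchmark runs | `seek_path` |
| CV folds | 10 | throughout |
| DE population / F / cr / budget | 4 / 0.9 / 0.9 / 10,000 | `DEConfig` |
| fitness weights w_M, w_C | 0.95, 0.05 | `DEConfig` |
| DE internal validation fraction | 0.2 | `DEConfig` |
| selection threshold | 1e-8 | `synthetic.SELECTION_THRESHOLD` |
| l1/2 smoothing eps | 1e-8 | `penalties.EPS_L12` |
| slope floor | 1e-12 | `penalties.SLOPE_FLOOR` |
| prediction clip | ±500 on the linear predictor | `predict_time` |

## 8. Problem sizes in tests and the acceptance script

The replicated reference comparison (lasso and the l1/2-type penalty) runs the
full 2200-feature, 600-sample design with 10-fold CV and 10 replicates — each
fit is seconds, so full scale is affordable. The DE-tuned CHR is not: one
fitness evaluation costs folds + 1 path fits, so a 10,000-evaluation budget at
full scale is outside any desk budget. Its acceptance test runs a scaled
design (20 groups, 150 samples — same group structure, same relevant
coefficients) at a reduced budget and checks the scale-robust sensitivity
band; the specificity reference is a function of the full null dimension
(2156) and does not transfer, so only a sanity bound is applied. Property
tests use small random problems throughout.

## 9. Known limitations

- The greedy path is an approximation to the penalized solution path; for the
  lasso it tracks coordinate descent closely (tested), for non-convex
  penalties it is a heuristic with no global guarantee — inherent to the
  method, not an implementation gap.
- The l1/2-type comparator's behaviour depends on the smoothing `eps`; smaller
  values strengthen the rich-get-richer collapse. `eps = 1e-8` is a fixed
  design choice, and its collapse behaviour at moderate correlation is
  stronger than some published l1/2 implementations that use larger smoothing
  or reweighting. A structural consequence: in the l1/2+l2 mixture the
  square-root term dominates the slope at zero (`alpha/(2 sqrt(eps))`, about
  2500 at the defaults), so feature *entry* is handicapped exactly as under
  pure l1/2 and the convex term never gets to express a grouping effect —
  under this solver and smoothing, l1/2+l2 selects like l1/2, unlike elastic
  net and CHR whose slopes at zero are O(1).
- DE fitness is noisy (a single 80/20 split); with the reference population of
  4 the search is closer to stochastic hill climbing than to a converged
  evolutionary optimum at small budgets.
- The concordance implementation is O(n^2) in memory and time; fine for
  hundreds to a few thousand samples, not for biobank scale.
- Imputation ignores covariates (marginal Kaplan-Meier), the standard choice
  for this estimator family; covariate-dependent censoring biases it.
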