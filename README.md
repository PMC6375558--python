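# chrde

Penalized accelerated failure time (AFT) survival models with **complex
harmonic regularization** and **differential-evolution hyperparameter
tuning**, for selecting grouped biomarkers from high-dimensional expression
data with right-censored outcomes.

## The problem

Survival studies with genomic covariates face three difficulties at once:

1. **Censoring.** Many subjects leave the study before the event; their
   outcome is only a lower bound. `chrde` fits a linear model on log survival
   time after replacing each censored response with its Kaplan-Meier
   conditional mean, turning the problem into penalized least squares.
2. **High dimension.** Thousands of genes, a few hundred samples. A sparsity
   penalty must drive most coefficients to exactly zero.
3. **Grouped signal.** Co-regulated genes are strongly correlated, and the
   biology usually wants the whole module, not one arbitrary representative.
   Purely sparse penalties (lasso, l1/2-type) pick one feature per group and
   drop the rest precisely when the correlation is strongest.

The complex harmonic regularization (CHR) penalty mixes a concave sparsity
component `m(beta; a)` — interpolating lasso to l1/2 as `a` goes 0 to 1 — with
a strictly convex grouping component `n(beta; b)` — interpolating ridge to
lasso as `b` goes 0 to 1 — weighted by `gamma`. The model is fit by a greedy
**path-seeking** solver (one coordinate per step, step length chosen to cut
the loss by 1%, stopping point chosen by 10-fold cross-validation), and the
hyperparameter triple `(a, b, gamma)` can be tuned globally by a **memetic
differential evolution** loop whose fitness combines validation error and
concordance. See [docs/methods.md](docs/methods.md) for the full description.

## Worked example

Simulate a grouped design (20 hub "key factors", each regulating 10 correlated
genes; 4 groups carry signal), fit a CHR-penalized AFT model, and score it on
held-out samples:

```python
import numpy as np
from chrde import PenalizedAFT, SyntheticDesign, generate

design = SyntheticDesign(n_kf=20, n_samples=150, rho=0.7, seed=0)
data, truth = generate(design)

rng = np.random.default_rng(1)
perm = rng.permutation(design.n_samples)
train, test = data.subset(perm[:100]), data.subset(perm[100:])

model = PenalizedAFT.from_dataset(train)
results = model.fit(penalty="chr", folds=5, max_steps=2000, seed=0)
print(results.summary())

metrics = results.score(test.tau, test.delta, test.X)
print(f"\nheld-out: mse={metrics['mse']:.3f}  ci={metrics['ci']:.3f}  "
      f"selected={metrics['n_selected']}")
```

Output:

```
Penalized AFT (path seeking)
============================================
penalty:            chr
hyperparameters:    a=0.5000  b=0.5000  gamma=0.5000
observations:       100  (events 75, censored 25)
features:           220
selected:           66
train loss (log):   22.1915
intercept:          -4.91492
CV stopping step:   207 (cv error 77.5882)
--------------------------------------------
top coefficients (|beta|, 10 shown)
  KF0004                   -2.68724
  KF0003                   +1.82518
  KF0003_G08               +1.36927
  KF0003_G05               +1.36797
  KF0004_G02               -1.33599
  KF0004_G07               -1.32505
  KF0004_G09               -1.14028
  KF0002                   -1.10456
  KF0003_G10               +0.91718
  KF0003_G07               +0.75698

held-out: mse=49.205  ci=0.941  selected=66
```

The top coefficients land on the relevant hubs (KF0001–KF0004) and their
genes — the grouping component pulls whole modules in together. To tune
`(a, b, gamma)` instead of fixing them, add the DE optimizer:

```python
from chrde import DEConfig
results = model.fit(penalty="chr", optimizer="de",
                    de_config=DEConfig(budget=100, seed=0, folds=5), seed=0)
```

Comparator penalties run through the same solver:
`model.fit(penalty="lasso")`, `"l12"`, `"enet"`, `"l12l2"`.

## Command line

```
chrde simulate --n-kf 20 --n-samples 150 --rho 0.7 --seed 0 --out sim
chrde fit --expression sim.expression.tsv --survival sim.survival.tsv \
          --penalty chr --folds 5 --out fitrun
chrde evaluate --coefficients fitrun.coefficients.tsv \
          --expression sim.expression.tsv --survival sim.survival.tsv
chrde benchmark --rhos 0.2,0.9 --methods lasso,l12 --replicates 10 --out table.tsv
```

Exit codes: 0 success, 1 user error (malformed input, bad options), 2 internal
error. `chrde fit --config cfg.yaml` reads options from YAML; unknown keys are
rejected.

## Layout

- `src/chrde/data.py` — survival data containers, Kaplan-Meier estimation,
  censored-response imputation, AFT loss and prediction
- `src/chrde/penalties.py` — CHR pair and comparator penalties behind one
  plugin contract
- `src/chrde/path.py` — greedy path-seeking solver and cross-validated
  stopping
- `src/chrde/evolve.py` — memetic differential evolution over `(a, b, gamma)`
- `src/chrde/model.py` — `PenalizedAFT` / `PenalizedAFTResults` interface
- `src/chrde/synthetic.py` — grouped survival benchmark generator and
  replicated harness
- `src/chrde/methods.py`, `io.py`, `cli.py` — benchmark method registry, file
  IO, command line
- `docs/methods.md` — model, algorithms, numerical choices, limitations
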