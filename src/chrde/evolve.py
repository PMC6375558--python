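"""Memetic differential evolution over the CHR hyperparameters.

Each chromosome uses an "intron + exon" layout: the intron is the CHR
hyperparameter triple (a, b, gamma), evolved globally by DE/rand/1 with binomial
crossover and a simplex-crossover local search; the exon is the coefficient
vector produced by the penalized path fit under that intron (the local-learning
step). Fitness combines validation mean squared error and Harrell's concordance
index,

    fitness_i = w_M * (1 - MSE_i / sum_pop MSE) + w_C * CI_i,

with the MSE normalised by the current population's MSE sum. Selection is
greedy (a trial replaces its target iff its fitness is >= the target's), so the
population never deteriorates and the best fitness is monotone non-decreasing.

The DE engine is generic over the fitness evaluation, so the operators can be
exercised with cheap synthetic objectives; `run_chrde` wires in the CHR path
fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ImputedDataset, SurvivalDataset, impute_censored
from .path import cross_validate_path, seek_path
from .penalties import ChrHyperparams, chr_plugin


@dataclass
class DEConfig:
    """Settings of the memetic DE loop.

    Defaults follow the reference experimental setup: population of 4, scaling
    factor F = 0.9, crossover rate 0.9, local-search weight 1, fitness weights
    (0.95, 0.05), evaluation budget 10,000.
    """

    pop_size: int = 4
    F: float = 0.9
    cr: float = 0.9
    w_l: float = 1.0
    w_m: float = 0.95
    w_c: float = 0.05
    lower: tuple = (0.01, 0.01, 0.0)
    upper: tuple = (0.99, 0.99, 1.0)
    budget: int = 10_000
    seed: int | None = None
    # local-learning (path fit) settings
    folds: int = 10
    max_steps: int | None = None
    val_fraction: float = 0.2
    metric_scale: str = "log"  # "log" or "time"; see docs/methods.md
    clip: float = 500.0

    def __post_init__(self):
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4 (DE/rand/1 needs 3 distinct others)")
        if not (0.0 <= self.cr <= 1.0):
            raise ValueError("cr must lie in [0, 1]")
        if abs(self.w_m + self.w_c - 1.0) > 1e-12:
            raise ValueError("fitness weights w_m + w_c must sum to 1")
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != hi.shape or np.any(lo >= hi):
            raise ValueError("bounds must satisfy lower < upper elementwise")

    @property
    def n_dims(self) -> int:
        return len(self.lower)


@dataclass
class Chromosome:
    """One DE individual: intron vector, its fitted exon, and fitness terms."""

    intron: np.ndarray
    mse: float = np.nan
    ci: float = np.nan
    fitness: float = -np.inf
    exon: np.ndarray | None = None


@dataclass
class Population:
    members: list[Chromosome] = field(default_factory=list)

    def matrix(self) -> np.ndarray:
        return np.array([m.intron for m in self.members])

    @property
    def best(self) -> Chromosome:
        return max(self.members, key=lambda m: m.fitness)

    def mse_sum(self) -> float:
        vals = [m.mse for m in self.members if np.isfinite(m.mse)]
        return float(np.sum(vals)) if vals else 0.0


def concordance_index(tau, delta, predicted_tau) -> float:
    """Harrell's concordance index for right-censored data.

    A pair (i, j) is comparable when tau_i < tau_j and subject i had an event.
    It is concordant when the predictions order the pair the same way
    (predicted_tau_i < predicted_tau_j); prediction ties count 1/2.
    """
    tau = np.asarray(tau, float)
    delta = np.asarray(delta, float)
    pred = np.asarray(predicted_tau, float)
    comparable = (tau[:, None] < tau[None, :]) & (delta[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs: concordance index is undefined")
    concordant = comparable & (pred[:, None] < pred[None, :])
    tied = comparable & (pred[:, None] == pred[None, :])
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def population_fitness(mse: float, ci: float, mse_sum: float, config: DEConfig) -> float:
    """Weighted fitness with population-normalised MSE; -inf for non-finite MSE."""
    if not np.isfinite(mse):
        return -np.inf
    ratio = mse / mse_sum if mse_sum > 0 else 0.0
    return config.w_m * (1.0 - ratio) + config.w_c * ci


# ---------------------------------------------------------------------------
# DE operators


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect out-of-bounds coordinates back into [lo, hi] (preserves diversity)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def de_mutant(pop_r, pop_s, pop_t, F: float, lower, upper) -> np.ndarray:
    """DE/rand/1 mutant pop_r + F (pop_s - pop_t), reflected into bounds."""
    child = np.asarray(pop_r, float) + F * (np.asarray(pop_s, float) - np.asarray(pop_t, float))
    return _reflect(child, np.asarray(lower, float), np.asarray(upper, float))


def mutate(population: Population, config: DEConfig, rng: np.random.Generator) -> np.ndarray:
    """One mutant vector per target, with r, s, t distinct from each other and the target."""
    mat = population.matrix()
    n = len(population.members)
    mutants = np.empty_like(mat)
    for i in range(n):
        choices = [j for j in range(n) if j != i]
        r, s, t = rng.choice(choices, size=3, replace=False)
        mutants[i] = de_mutant(mat[r], mat[s], mat[t], config.F, config.lower, config.upper)
    return mutants


def crossover(target, mutant, config: DEConfig, rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover; the forced j_rand component guarantees at least one
    coordinate from the mutant."""
    target = np.asarray(target, float)
    mutant = np.asarray(mutant, float)
    nd = len(target)
    j_rand = int(rng.integers(nd))
    mask = rng.random(nd) < config.cr
    mask[j_rand] = True
    return np.where(mask, mutant, target)


def select(target: Chromosome, trial: Chromosome) -> Chromosome:
    """Greedy >= selection: the trial survives iff its fitness is not worse."""
    return trial if trial.fitness >= target.fitness else target


def simplex_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Simplex-crossover weights r_j = u^(1/(j+1)), j = 1..n, u ~ U(0,1)."""
    u = rng.random(n)
    exponents = 1.0 / (np.arange(1, n + 1) + 1.0)
    return u**exponents


def local_search_candidate(
    tmp: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Recursive simplex-crossover combination over the expanded population.

    C_1 = 0; C_j = r_{j-1} (tmp_{j-1} - tmp_j + C_{j-1}); candidate = tmp_N + C_N.
    """
    n = tmp.shape[0]
    C = np.zeros(tmp.shape[1])
    for j in range(1, n):
        C = weights[j - 1] * (tmp[j - 1] - tmp[j] + C)
    return tmp[n - 1] + C


def adaptive_local_search(
    population: Population,
    config: DEConfig,
    rng: np.random.Generator,
    evaluate,
    budget_left: int,
) -> int:
    """Simplex-crossover neighbourhood search around the population centroid.

    The population is expanded about its mean by w_L; for each slot a candidate
    is built from the recursive combination and accepted only when it lies
    within bounds and its fitness is >= the incumbent's. Returns the number of
    fitness evaluations spent.
    """
    lo = np.asarray(config.lower, float)
    hi = np.asarray(config.upper, float)
    mat = population.matrix()
    mean = mat.mean(axis=0)
    tmp = mean + config.w_l * (mat - mean)
    n = len(population.members)
    evals = 0
    for i in range(n):
        weights = simplex_weights(n - 1, rng)
        cand = local_search_candidate(tmp, weights)
        if np.any(cand < lo) or np.any(cand > hi):
            continue  # rejected silently: out of bounds
        if evals >= budget_left:
            break
        trial = evaluate(cand, population)
        evals += 1
        if trial.fitness >= population.members[i].fitness:
            population.members[i] = trial
    return evals


def init_population(
    config: DEConfig, rng: np.random.Generator, evaluate
) -> tuple[Population, int]:
    """Uniform initial population within bounds, each member evaluated."""
    lo = np.asarray(config.lower, float)
    hi = np.asarray(config.upper, float)
    mat = rng.random((config.pop_size, config.n_dims)) * (hi - lo) + lo
    pop = Population()
    # first pass: raw objectives, then fitness with the full-population MSE sum
    raws = [evaluate.raw(mat[i]) for i in range(config.pop_size)]
    mse_sum = float(np.sum([r[0] for r in raws if np.isfinite(r[0])]))
    for intron, (mse, ci, exon) in zip(mat, raws):
        pop.members.append(
            Chromosome(
                intron=intron.copy(),
                mse=mse,
                ci=ci,
                fitness=population_fitness(mse, ci, mse_sum, config),
                exon=exon,
            )
        )
    return pop, config.pop_size


# ---------------------------------------------------------------------------
# CHR fitness and the full loop


class ChrFitness:
    """Local-learning step: path fit + CV selection under a candidate intron.

    The training data is split once (seeded) into an internal fit/validation
    pair; MSE and concordance are measured on the validation part so the
    evolving hyperparameters are scored on data the path fit did not see.
    """

    def __init__(self, data: ImputedDataset, config: DEConfig, cv_seed: int):
        self.config = config
        self.cv_seed = cv_seed
        rng = np.random.default_rng(cv_seed)
        h = data.n_samples
        perm = rng.permutation(h)
        n_val = max(2, int(round(config.val_fraction * h)))
        self.val_idx = perm[:n_val]
        self.fit_idx = perm[n_val:]
        self.data = data
        self.fit_data = ImputedDataset(
            data.X[self.fit_idx],
            data.y[self.fit_idx],
            delta=None if data.delta is None else data.delta[self.fit_idx],
            tau=None if data.tau is None else data.tau[self.fit_idx],
        )
        self.n_evals = 0

    def _fit_beta(self, intron, data: ImputedDataset) -> np.ndarray:
        params = ChrHyperparams(*np.asarray(intron, float))
        plugin = chr_plugin(params)
        cfg = self.config
        trace = seek_path(data, plugin, max_steps=cfg.max_steps)
        sel = cross_validate_path(
            data, plugin, trace, folds=cfg.folds, max_steps=cfg.max_steps,
            seed=self.cv_seed,
        )
        return sel.point.beta

    def raw(self, intron) -> tuple[float, float, np.ndarray]:
        """(validation MSE, validation CI, fitted exon) for one intron."""
        self.n_evals += 1
        beta = self._fit_beta(intron, self.fit_data)
        X_val = self.data.X[self.val_idx]
        lin = X_val @ beta
        cfg = self.config
        if cfg.metric_scale == "log":
            err = self.data.y[self.val_idx] - lin
            mse = float(err @ err) / len(self.val_idx)
        else:
            tau_val = self.data.tau[self.val_idx]
            pred = np.exp(np.clip(lin, -cfg.clip, cfg.clip))
            mse = float(np.mean((tau_val - pred) ** 2))
        tau_val = self.data.tau[self.val_idx]
        delta_val = self.data.delta[self.val_idx]
        ci = concordance_index(tau_val, delta_val, lin)
        return mse, ci, beta

    def __call__(self, intron, population: Population) -> Chromosome:
        mse, ci, exon = self.raw(intron)
        fit = population_fitness(mse, ci, population.mse_sum(), self.config)
        return Chromosome(np.asarray(intron, float).copy(), mse, ci, fit, exon)


@dataclass
class ChrDeResult:
    """Best intron found by DE, its full-data refit exon, and the search history."""

    hyperparams: ChrHyperparams
    beta: np.ndarray
    history: list  # (generation, best_fitness, best_intron) tuples
    n_evals: int
    population: Population


def run_de(config: DEConfig, evaluate) -> tuple[Population, list, int]:
    """Generic memetic DE loop over any (mse, ci, payload) objective."""
    if config.budget < config.pop_size:
        raise ValueError("evaluation budget smaller than the population size")
    rng = np.random.default_rng(config.seed)
    pop, n_evals = init_population(config, rng, evaluate)
    history = [(0, pop.best.fitness, pop.best.intron.copy())]
    generation = 0
    while n_evals < config.budget:
        generation += 1
        mutants = mutate(pop, config, rng)
        for i in range(config.pop_size):
            if n_evals >= config.budget:
                break
            trial_vec = crossover(pop.members[i].intron, mutants[i], config, rng)
            trial = evaluate(trial_vec, pop)
            n_evals += 1
            pop.members[i] = select(pop.members[i], trial)
        if n_evals < config.budget:
            n_evals += adaptive_local_search(
                pop, config, rng, evaluate, config.budget - n_evals
            )
        history.append((generation, pop.best.fitness, pop.best.intron.copy()))
    return pop, history, n_evals


def run_chrde(data: SurvivalDataset | ImputedDataset, config: DEConfig) -> ChrDeResult:
    """Full CHR-DE loop: impute, evolve the intron, refit the exon.

    Returns the best individual's hyperparameters, its coefficient vector refit
    on the complete training data, and the per-generation best-fitness history.
    """
    imputed = impute_censored(data) if isinstance(data, SurvivalDataset) else data
    seed_rng = np.random.default_rng(config.seed)
    cv_seed = int(seed_rng.integers(2**31))
    evaluate = ChrFitness(imputed, config, cv_seed)
    pop, history, n_evals = run_de(config, evaluate)

    best = pop.best
    params = ChrHyperparams(*best.intron)
    plugin = chr_plugin(params)
    trace = seek_path(imputed, plugin, max_steps=config.max_steps)
    sel = cross_validate_path(
        imputed, plugin, trace, folds=config.folds, max_steps=config.max_steps,
        seed=cv_seed,
    )
    return ChrDeResult(
        hyperparams=params,
        beta=sel.point.beta,
        history=history,
        n_evals=n_evals,
        population=pop,
    )
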