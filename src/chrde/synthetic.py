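"""Synthetic grouped gene-expression benchmark with censored survival outcomes.

The generator emulates a regulatory-module structure: `n_kf` key factors (KFs),
each drawn i.i.d. N(0,1), each regulating `genes_per_kf` genes from the
conditional normal

    gene | KF  ~  N(rho * KF, 1 - rho^2),

the standard hub-and-spokes expression simulation: each gene has unit marginal
variance and corr(gene, KF) = rho exactly. (`correlation="mixing"` instead uses
the literal mixture gene = rho*KF + (1-rho)*z, inducing
corr = rho / sqrt(rho^2 + (1-rho)^2).) The first four
groups (4 KFs + their 40 genes = 44 variables at defaults) carry signal with
coefficient pattern (c, c/sqrt(10) * 10) for c in (2, -2, 4, -4); the remaining
groups are null. The log survival time is

    Y = X_relevant . beta_true + eps,  eps ~ N(0, 1),

observed times are tau = exp(min(Y, Y_c)) with independent log-normal censoring
times calibrated to a target censoring fraction. Feature selections are scored
by sensitivity (truly relevant features selected / number relevant) and
specificity (truly null features rejected / number null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalDataset


@dataclass
class SyntheticDesign:
    """Parameters of the grouped simulation design.

    Defaults give the 200 x (1 + 10) = 2200-variable design with 44 relevant
    variables, 600 samples, a 2/3 train fraction and 30% censoring.
    """

    n_kf: int = 200
    genes_per_kf: int = 10
    n_relevant_groups: int = 4
    rho: float = 0.5
    n_samples: int = 600
    train_fraction: float = 2.0 / 3.0
    censor_rate: float = 0.3
    noise_sd: float = 1.0
    kf_coefficients: tuple = (2.0, -2.0, 4.0, -4.0)
    correlation: str = "conditional"  # "conditional" (corr = rho) or "mixing"
    seed: int | None = None

    def __post_init__(self):
        if self.n_kf < self.n_relevant_groups:
            raise ValueError("need at least n_relevant_groups key factors")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if len(self.kf_coefficients) != self.n_relevant_groups:
            raise ValueError("one coefficient per relevant group required")
        if self.correlation not in ("conditional", "mixing"):
            raise ValueError("correlation must be 'conditional' or 'mixing'")

    @property
    def n_features(self) -> int:
        return self.n_kf * (1 + self.genes_per_kf)

    @property
    def n_relevant(self) -> int:
        return self.n_relevant_groups * (1 + self.genes_per_kf)


@dataclass
class GroundTruth:
    """True coefficient vector and its support."""

    beta_true: np.ndarray
    support: np.ndarray  # indices of nonzero coefficients

    @property
    def n_relevant(self) -> int:
        return len(self.support)


def true_beta(design: SyntheticDesign) -> GroundTruth:
    """Group-patterned coefficients: KF gets c, its genes each get c/sqrt(g)."""
    g = design.genes_per_kf
    beta = np.zeros(design.n_features)
    for u, c in enumerate(design.kf_coefficients):
        start = u * (1 + g)
        beta[start] = c
        beta[start + 1 : start + 1 + g] = c / np.sqrt(g)
    return GroundTruth(beta_true=beta, support=np.flatnonzero(beta))


def generate(design: SyntheticDesign) -> tuple[SurvivalDataset, GroundTruth]:
    """Draw one dataset from the design.

    Columns are laid out group-by-group: [KF_1, its genes..., KF_2, ...], so the
    relevant variables are the first ``n_relevant`` columns.
    """
    rng = np.random.default_rng(design.seed)
    n, g = design.n_samples, design.genes_per_kf
    kf = rng.standard_normal((n, design.n_kf))
    z = rng.standard_normal((n, design.n_kf, g))
    if design.correlation == "conditional":
        z_scale = np.sqrt(1.0 - design.rho**2)
    else:  # literal mixture form
        z_scale = 1.0 - design.rho
    genes = design.rho * kf[:, :, None] + z_scale * z
    # interleave KF and its genes: shape (n, n_kf, 1+g) -> flat
    X = np.concatenate([kf[:, :, None], genes], axis=2).reshape(n, -1)

    truth = true_beta(design)
    eps = design.noise_sd * rng.standard_normal(n)
    Y = X[:, truth.support] @ truth.beta_true[truth.support] + eps

    if design.censor_rate > 0:
        zc = rng.standard_normal(n)
        # mu_c such that the empirical censoring fraction hits the target:
        # censored iff mu_c + zc < Y, i.e. mu_c below the (1-q) quantile of Y - zc
        w = Y - zc
        mu_c = float(np.quantile(w, 1.0 - design.censor_rate))
        Yc = mu_c + zc
        delta = (Y <= Yc).astype(float)
        tau = np.exp(np.minimum(Y, Yc))
    else:
        delta = np.ones(n)
        tau = np.exp(Y)

    names = []
    for u in range(design.n_kf):
        names.append(f"KF{u + 1:04d}")
        names.extend(f"KF{u + 1:04d}_G{i + 1:02d}" for i in range(g))
    data = SurvivalDataset(X, tau, delta, feature_names=names)
    return data, truth


def sensitivity(selected, truth: GroundTruth) -> float:
    """Fraction of truly relevant features that were selected."""
    selected = np.asarray(list(selected), dtype=int)
    return float(np.isin(truth.support, selected).sum()) / truth.n_relevant


def specificity(selected, truth: GroundTruth) -> float:
    """Fraction of truly null features that were rejected."""
    selected = set(int(i) for i in selected)
    n_total = len(truth.beta_true)
    null = [j for j in range(n_total) if truth.beta_true[j] == 0.0]
    rejected = sum(1 for j in null if j not in selected)
    return rejected / len(null)


#: coefficients below this magnitude count as not selected
SELECTION_THRESHOLD = 1e-8


def selected_indices(beta_penalized: np.ndarray) -> np.ndarray:
    """Indices of features with |beta| above the selection threshold.

    ``beta_penalized`` excludes the intercept.
    """
    return np.flatnonzero(np.abs(beta_penalized) > SELECTION_THRESHOLD)


@dataclass
class BenchmarkResult:
    """Replicate-level and aggregated benchmark metrics."""

    replicates: pd.DataFrame  # one row per (method, rho, replicate)
    table: pd.DataFrame  # mean and standard error per (method, rho)
    failures: list = field(default_factory=list)


def _aggregate(rep_df: pd.DataFrame) -> pd.DataFrame:
    metrics = ["sensitivity", "specificity", "mse", "ci"]
    grouped = rep_df.groupby(["method", "rho"])[metrics]
    mean = grouped.mean()
    se = grouped.sem(ddof=1)
    out = pd.concat({"mean": mean, "se": se}, axis=1)
    out.columns = [f"{m}_{stat}" for stat, m in out.columns]
    return out.reset_index()


def benchmark(
    design: SyntheticDesign,
    methods: dict,
    n_replicates: int = 10,
    seed: int | None = None,
    rhos: tuple | None = None,
) -> BenchmarkResult:
    """Run registered fitting methods over replicated draws of the design.

    ``methods`` maps a method name to a callable
    ``fn(train: SurvivalDataset, test: SurvivalDataset, seed: int) -> dict``
    returning at least ``selected`` (feature indices); optional keys ``mse`` and
    ``ci`` are carried into the table. Each replicate draws a fresh dataset and
    a fresh 2/3-train / 1/3-test split. Replicate failures are recorded, not
    fatal; their cells stay missing.
    """
    if rhos is None:
        rhos = (design.rho,)
    master = np.random.SeedSequence(seed)
    rows = []
    failures = []
    for rho in rhos:
        rho_seeds = master.spawn(1)[0].generate_state(n_replicates) % (2**31)
        for rep in range(n_replicates):
            rep_seed = int(rho_seeds[rep])
            d = SyntheticDesign(
                **{
                    **{f: getattr(design, f) for f in (
                        "n_kf", "genes_per_kf", "n_relevant_groups", "n_samples",
                        "train_fraction", "censor_rate", "noise_sd",
                        "kf_coefficients", "correlation",
                    )},
                    "rho": rho,
                    "seed": rep_seed,
                }
            )
            data, truth = generate(d)
            rng = np.random.default_rng(rep_seed + 1)
            perm = rng.permutation(d.n_samples)
            n_train = int(round(d.train_fraction * d.n_samples))
            train = data.subset(perm[:n_train])
            test = data.subset(perm[n_train:])
            for name, fn in methods.items():
                try:
                    out = fn(train, test, rep_seed)
                    sel = np.asarray(out["selected"], dtype=int)
                    rows.append(
                        {
                            "method": name,
                            "rho": rho,
                            "replicate": rep,
                            "sensitivity": sensitivity(sel, truth),
                            "specificity": specificity(sel, truth),
                            "mse": out.get("mse", np.nan),
                            "ci": out.get("ci", np.nan),
                            "n_selected": len(sel),
                        }
                    )
                except Exception as exc:  # noqa: BLE001 - record, keep going
                    failures.append((name, rho, rep, repr(exc)))
    rep_df = pd.DataFrame(rows)
    table = _aggregate(rep_df) if len(rep_df) else pd.DataFrame()
    return BenchmarkResult(replicates=rep_df, table=table, failures=failures)
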