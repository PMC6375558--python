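"""Registry of benchmark-ready fitting methods.

Each entry wraps the Model/Results API into the callable signature the
synthetic benchmark harness expects:
``fn(train, test, seed) -> {"selected", "mse", "ci", ...}``.
"""

from __future__ import annotations

from .evolve import DEConfig
from .model import PenalizedAFT
from .penalties import ChrHyperparams


def penalty_method(
    penalty: str,
    hyperparams: ChrHyperparams | None = None,
    alpha: float | str = 0.5,
    folds: int = 10,
    max_steps: int | None = None,
    metric_scale: str = "log",
):
    """Benchmark callable for a fixed-penalty path-seeking fit."""

    def fn(train, test, seed):
        model = PenalizedAFT.from_dataset(train)
        res = model.fit(
            penalty=penalty, hyperparams=hyperparams, alpha=alpha,
            folds=folds, max_steps=max_steps, seed=seed,
        )
        score = res.score(test.tau, test.delta, test.X, metric_scale=metric_scale)
        return {"selected": res.selected, **score}

    return fn


def chrde_method(
    de_config: DEConfig | None = None,
    folds: int = 10,
    max_steps: int | None = None,
    metric_scale: str = "log",
    **de_kwargs,
):
    """Benchmark callable for the DE-tuned CHR fit."""

    def fn(train, test, seed):
        cfg = de_config or DEConfig(
            seed=seed, folds=folds, max_steps=max_steps, **de_kwargs
        )
        if de_config is not None:
            cfg.seed = seed
        model = PenalizedAFT.from_dataset(train)
        res = model.fit(penalty="chr", optimizer="de", de_config=cfg, seed=seed)
        score = res.score(test.tau, test.delta, test.X, metric_scale=metric_scale)
        return {"selected": res.selected, **score}

    return fn


def oracle_method(truth):
    """Reference method that returns the true support (harness sanity check)."""

    def fn(train, test, seed):
        return {"selected": truth.support}

    return fn


def get_methods(names, folds: int = 10, max_steps: int | None = None, **chrde_kwargs):
    """Build a name -> callable dict for the benchmark harness."""
    out = {}
    for name in names:
        if name in ("lasso", "l12", "enet", "l12l2", "chr"):
            out[name] = penalty_method(name, folds=folds, max_steps=max_steps)
        elif name == "chr-de":
            out[name] = chrde_method(folds=folds, max_steps=max_steps, **chrde_kwargs)
        else:
            raise ValueError(f"unknown method {name!r}")
    return out
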