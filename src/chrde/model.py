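"""Model / Results interface over the penalized AFT machinery.

`PenalizedAFT` is constructed from right-censored survival data (times, event
indicators, covariates); `fit` runs Kaplan–Meier mean imputation, grows the
penalized coefficient path, picks the stopping point by cross-validation and —
optionally — tunes the CHR hyperparameters globally with the memetic
differential-evolution loop. The returned `PenalizedAFTResults` carries the
coefficient estimates, the selected feature set, the path and CV diagnostics,
and prediction/scoring helpers.

Example
-------
>>> model = PenalizedAFT(tau, delta, X, feature_names=genes)
>>> res = model.fit(penalty="chr", optimizer="de", seed=0)
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import SurvivalDataset, aft_loss, impute_censored, predict_time
from .evolve import ChrDeResult, DEConfig, concordance_index, run_chrde
from .path import CVSelection, PathTrace, cross_validate_path, seek_path
from .penalties import ChrHyperparams, get_plugin
from .synthetic import SELECTION_THRESHOLD

#: CHR hyperparameters used when none are given and no optimizer runs
DEFAULT_CHR = ChrHyperparams(a=0.5, b=0.5, gamma=0.5)
#: mixing-weight grid tried when alpha="cv" for the elastic-net family
ALPHA_GRID = (0.2, 0.5, 0.8)


class PenalizedAFT:
    """Penalized accelerated failure time model for right-censored data.

    Parameters
    ----------
    tau : array of observed times (> 0)
    delta : array of event indicators (1 = event, 0 = censored)
    exog : (h, k) covariate matrix without intercept
    feature_names : optional feature labels
    """

    def __init__(self, tau, delta, exog, feature_names=None, sample_ids=None):
        self.data = SurvivalDataset(
            np.asarray(exog, float), tau, delta,
            feature_names=feature_names, sample_ids=sample_ids,
        )
        self.imputed = impute_censored(self.data)

    @classmethod
    def from_dataset(cls, dataset: SurvivalDataset) -> "PenalizedAFT":
        return cls(
            dataset.tau, dataset.delta, dataset.X,
            feature_names=dataset.feature_names, sample_ids=dataset.sample_ids,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time_col: str = "time", event_col: str = "event"
    ) -> "PenalizedAFT":
        """Build from a dataframe whose remaining columns are covariates."""
        covar = df.drop(columns=[time_col, event_col])
        return cls(
            df[time_col].to_numpy(),
            df[event_col].to_numpy(),
            covar.to_numpy(dtype=float),
            feature_names=list(covar.columns),
            sample_ids=[str(i) for i in df.index],
        )

    @property
    def feature_names(self):
        return self.data.feature_names

    def fit(
        self,
        penalty: str = "chr",
        hyperparams: ChrHyperparams | None = None,
        alpha: float | str = 0.5,
        optimizer: str | None = None,
        de_config: DEConfig | None = None,
        folds: int = 10,
        max_steps: int | None = None,
        seed: int | None = None,
    ) -> "PenalizedAFTResults":
        """Fit the penalized path and select the stopping point by CV.

        ``optimizer="de"`` (CHR penalty only) evolves (a, b, gamma) with the
        memetic DE loop before the final refit; ``optimizer=None`` fits at the
        given (or default) hyperparameters — the plain path-seeking baseline.
        ``alpha`` is the elastic-net-family mixing weight; pass "cv" to choose
        it from a small grid by cross-validated error.
        """
        if optimizer not in (None, "none", "de"):
            raise ValueError("optimizer must be None or 'de'")
        if optimizer == "de":
            if penalty != "chr":
                raise ValueError("the DE optimizer applies to the chr penalty only")
            config = de_config or DEConfig(seed=seed, folds=folds, max_steps=max_steps)
            if de_config is None:
                config.seed = seed
            de_result = run_chrde(self.imputed, config)
            plugin = get_plugin("chr", de_result.hyperparams)
            trace = seek_path(self.imputed, plugin, max_steps=config.max_steps)
            cv = cross_validate_path(
                self.imputed, plugin, trace, folds=config.folds,
                max_steps=config.max_steps, seed=seed,
            )
            return PenalizedAFTResults(
                self, de_result.beta, penalty, de_result.hyperparams,
                trace=trace, cv=cv, de_result=de_result,
            )

        if penalty == "chr" and hyperparams is None:
            hyperparams = DEFAULT_CHR
        if penalty in ("enet", "l12l2") and alpha == "cv":
            alpha = self._tune_alpha(penalty, folds, max_steps, seed)
        plugin = get_plugin(penalty, hyperparams, alpha if alpha != "cv" else 0.5)
        trace = seek_path(self.imputed, plugin, max_steps=max_steps)
        cv = cross_validate_path(
            self.imputed, plugin, trace, folds=folds, max_steps=max_steps, seed=seed
        )
        return PenalizedAFTResults(
            self, cv.point.beta, penalty, hyperparams, alpha=alpha, trace=trace, cv=cv
        )

    def _tune_alpha(self, penalty, folds, max_steps, seed) -> float:
        best_alpha, best_err = ALPHA_GRID[0], np.inf
        for a in ALPHA_GRID:
            plugin = get_plugin(penalty, alpha=a)
            trace = seek_path(self.imputed, plugin, max_steps=max_steps)
            cv = cross_validate_path(
                self.imputed, plugin, trace, folds=folds, max_steps=max_steps, seed=seed
            )
            err = cv.cv_errors.min()
            if err < best_err:
                best_alpha, best_err = a, err
        return best_alpha


class PenalizedAFTResults:
    """Estimates, diagnostics and prediction helpers of a penalized AFT fit."""

    def __init__(
        self,
        model: PenalizedAFT,
        params: np.ndarray,
        penalty: str,
        hyperparams: ChrHyperparams | None = None,
        alpha: float | None = None,
        trace: PathTrace | None = None,
        cv: CVSelection | None = None,
        de_result: ChrDeResult | None = None,
    ):
        self.model = model
        self.params = np.asarray(params, float)  # (k+1,), intercept first
        self.penalty = penalty
        self.hyperparams = hyperparams
        self.alpha = alpha
        self.trace = trace
        self.cv = cv
        self.de_result = de_result

    # -- estimates -------------------------------------------------------
    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.params[1:], index=self.model.feature_names, name="beta")

    @property
    def selected(self) -> np.ndarray:
        """Indices of features with |beta| above the selection threshold."""
        return np.flatnonzero(np.abs(self.params[1:]) > SELECTION_THRESHOLD)

    @property
    def selected_features(self) -> list[str]:
        return [self.model.feature_names[j] for j in self.selected]

    @property
    def train_loss(self) -> float:
        return aft_loss(self.params, self.model.imputed)

    @property
    def history(self):
        """Per-generation (generation, best fitness, best intron) DE history."""
        return None if self.de_result is None else self.de_result.history

    # -- prediction / scoring -------------------------------------------
    def predict(self, X, clip: float = 500.0) -> np.ndarray:
        """Predicted survival times exp(linear predictor)."""
        return predict_time(self.params, X, clip=clip)

    def linear_predictor(self, X) -> np.ndarray:
        return self.params[0] + np.asarray(X, float) @ self.params[1:]

    def score(self, tau, delta, X, metric_scale: str = "log", clip: float = 500.0) -> dict:
        """Held-out MSE and concordance index.

        ``metric_scale="log"`` measures squared error between log observed time
        and the linear predictor; ``"time"`` between observed time and the
        (clipped) exponentiated prediction.
        """
        tau = np.asarray(tau, float)
        lin = self.linear_predictor(X)
        if metric_scale == "log":
            mse = float(np.mean((np.log(tau) - lin) ** 2))
        elif metric_scale == "time":
            mse = float(np.mean((tau - np.exp(np.clip(lin, -clip, clip))) ** 2))
        else:
            raise ValueError("metric_scale must be 'log' or 'time'")
        ci = concordance_index(tau, delta, lin)
        return {"mse": mse, "ci": ci, "n_selected": int(len(self.selected))}

    # -- reporting -------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        h, k = self.model.data.X.shape
        n_events = int(self.model.data.delta.sum())
        lines = [
            "Penalized AFT (path seeking)",
            "=" * 44,
            f"penalty:            {self.penalty}",
        ]
        if self.hyperparams is not None:
            p = self.hyperparams
            lines.append(
                f"hyperparameters:    a={p.a:.4f}  b={p.b:.4f}  gamma={p.gamma:.4f}"
            )
        if self.alpha is not None and self.penalty in ("enet", "l12l2"):
            lines.append(f"mixing alpha:       {self.alpha}")
        lines += [
            f"observations:       {h}  (events {n_events}, censored {h - n_events})",
            f"features:           {k}",
            f"selected:           {len(self.selected)}",
            f"train loss (log):   {self.train_loss:.6g}",
            f"intercept:          {self.intercept:.6g}",
        ]
        if self.cv is not None:
            lines.append(
                f"CV stopping step:   {self.cv.point.step_index} "
                f"(cv error {self.cv.cv_errors[self.cv.point.step_index]:.6g})"
            )
        coefs = self.coefficients
        nz = coefs[coefs.abs() > SELECTION_THRESHOLD]
        nz = nz.reindex(nz.abs().sort_values(ascending=False).index)[:top]
        if len(nz):
            lines.append("-" * 44)
            lines.append(f"top coefficients (|beta|, {len(nz)} shown)")
            for name, val in nz.items():
                lines.append(f"  {name:<24s} {val:+.5f}")
        return "\n".join(lines)

    def plot_fitness_history(self, ax=None):
        """Best-fitness-per-generation curve of the DE run (requires a DE fit)."""
        if self.de_result is None:
            raise ValueError("no DE history: fit with optimizer='de'")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        gens = [g for g, _, _ in self.de_result.history]
        best = [f for _, f, _ in self.de_result.history]
        ax.plot(gens, best, marker="o", ms=3)
        ax.set_xlabel("generation")
        ax.set_ylabel("best fitness")
        ax.set_title("memetic DE search")
        return ax
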