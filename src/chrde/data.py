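"""Right-censored survival data, Kaplan–Meier imputation and the AFT least-squares loss.

The accelerated failure time (AFT) model used throughout this package is a linear
model on log time,

    log(tau_i) = beta_0 + x_i . beta + eps_i,

fit by least squares after replacing each right-censored response with its
Kaplan–Meier conditional mean (Datta-style mean imputation): a censored subject's
log-time is imputed as the KM-weighted average of the log event times beyond its
censoring time, normalised by the survival probability at that time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SurvivalDataset:
    """Covariates plus right-censored survival outcomes.

    Parameters
    ----------
    X : ndarray, shape (h, k)
        Covariate matrix, one row per sample. No intercept column: the library
        prepends it where needed.
    tau : ndarray, shape (h,)
        Observed times, strictly positive (min of event and censoring time).
    delta : ndarray, shape (h,)
        Event indicators: 1 = event observed, 0 = right-censored.
    feature_names, sample_ids : optional label sequences.
    """

    X: np.ndarray
    tau: np.ndarray
    delta: np.ndarray
    feature_names: list[str] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (samples x features)")
        h = self.X.shape[0]
        if len(self.tau) != h or len(self.delta) != h:
            raise ValueError(
                f"length mismatch: X has {h} rows, tau {len(self.tau)}, delta {len(self.delta)}"
            )
        if h == 0:
            raise ValueError("empty dataset")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite entries")
        if np.any(self.tau <= 0) or np.any(~np.isfinite(self.tau)):
            raise ValueError("all observed times must be finite and > 0")
        if not np.all(np.isin(self.delta, (0.0, 1.0))):
            raise ValueError("delta must contain only 0 (censored) and 1 (event)")
        if self.feature_names is None:
            self.feature_names = [f"x{j}" for j in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match number of columns")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(h)]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            self.X[idx],
            self.tau[idx],
            self.delta[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
        )


@dataclass
class KaplanMeierCurve:
    """Product-limit estimate of the survival function.

    ``event_times`` holds the distinct times with at least one event, ascending;
    ``survival`` the estimate immediately after each such time; ``steps`` the
    positive probability mass dropped at each event time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    steps: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) immediately after time t (right-continuous)."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


@dataclass
class ImputedDataset:
    """Design matrix with leading intercept column and imputed log-time responses."""

    X: np.ndarray  # (h, k+1), column 0 all ones
    y: np.ndarray  # (h,) imputed log-scale responses
    feature_names: list[str] = field(default_factory=list)
    delta: np.ndarray | None = None
    tau: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_penalized(self) -> int:
        """Number of penalized coefficients (excludes the intercept)."""
        return self.X.shape[1] - 1


def kaplan_meier(tau, delta) -> KaplanMeierCurve:
    """Kaplan–Meier product-limit estimator.

    Ties of events and censorings at the same time are handled events-first
    (censored subjects at time t are still at risk for events at t).
    """
    tau = np.asarray(tau, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if tau.size == 0:
        raise ValueError("empty input")
    if len(tau) != len(delta):
        raise ValueError("tau and delta must have equal length")
    if np.any(tau <= 0):
        raise ValueError("times must be > 0")

    order = np.argsort(tau, kind="stable")
    t_sorted = tau[order]
    d_sorted = delta[order]

    times, first = np.unique(t_sorted, return_index=True)
    n = len(tau)
    event_times = []
    survival = []
    steps = []
    s = 1.0
    for t, i0 in zip(times, first):
        at_risk = n - i0
        mask = t_sorted == t
        n_events = int(d_sorted[mask].sum())
        if n_events == 0:
            continue
        s_new = s * (1.0 - n_events / at_risk)
        event_times.append(t)
        survival.append(s_new)
        steps.append(s - s_new)
        s = s_new
    if not event_times:
        warnings.warn("all observations censored: KM curve is flat at 1", stacklevel=2)
    return KaplanMeierCurve(
        np.asarray(event_times), np.asarray(survival), np.asarray(steps)
    )


def impute_censored(data: SurvivalDataset) -> ImputedDataset:
    """Replace censored responses with KM conditional means of later log event times.

    Events keep y_i = log(tau_i). A censored subject at tau_i gets

        y_i = S(tau_i)^{-1} * sum_{t_(r) > tau_i} log(t_(r)) * dS(t_(r)),

    the KM-weighted mean of log event times beyond tau_i. A censored subject with
    no event time beyond it falls back to y_i = log(tau_i).
    """
    km = kaplan_meier(data.tau, data.delta)
    y = np.log(data.tau)
    censored = np.flatnonzero(data.delta == 0)
    if censored.size and km.event_times.size:
        log_t = np.log(km.event_times)
        for i in censored:
            beyond = km.event_times > data.tau[i]
            if not np.any(beyond):
                continue  # fallback: keep log(tau_i)
            s_i = km.survival_at(data.tau[i])
            if s_i <= 0:
                continue
            y[i] = np.dot(log_t[beyond], km.steps[beyond]) / s_i
    X1 = np.column_stack([np.ones(data.n_samples), data.X])
    return ImputedDataset(
        X1, y, feature_names=list(data.feature_names), delta=data.delta.copy(),
        tau=data.tau.copy(),
    )


def aft_loss(beta, data: ImputedDataset) -> float:
    """Mean squared residual of the AFT fit on the imputed log scale."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != data.X.shape[1]:
        raise ValueError(
            f"beta has {beta.shape[0]} entries, expected {data.X.shape[1]} (incl. intercept)"
        )
    r = data.y - data.X @ beta
    return float(r @ r) / data.n_samples


def predict_time(beta, X, clip: float = 500.0):
    """Predicted survival times exp(beta_0 + X beta).

    ``X`` is the raw covariate matrix without intercept column; ``beta`` includes
    the intercept as entry 0. The linear predictor is clipped at ``±clip`` (with a
    warning) to guard exp overflow.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    lin = beta[0] + X @ beta[1:]
    if np.any(np.abs(lin) > clip):
        warnings.warn(
            f"linear predictor exceeds ±{clip}; predictions clipped", stacklevel=2
        )
        lin = np.clip(lin, -clip, clip)
    return np.exp(lin)
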