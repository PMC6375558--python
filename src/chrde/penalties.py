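"""Penalty plugins for the path-seeking solver.

The centrepiece is the complex harmonic regularization (CHR) pair

    m(beta; a) = sqrt( (2/(a(a+1))) |beta|   + ((1-a)/a)^2 ) - (1-a)/a,   0 < a < 1,
    n(beta; b) = sqrt( (2/(b(b+1))) |beta|^2 + ((1-b)/b)^2 ) - (1-b)/b,   0 < b < 1,

combined as  P(beta) = gamma * sum_j m(beta_j) + (1-gamma) * sum_j n(beta_j).

m interpolates between the Lasso (a -> 0: m ~ |beta|) and the l_1/2 penalty
(a -> 1: m -> sqrt|beta|); n between ridge (b -> 0: n ~ beta^2) and the Lasso
(b -> 1: n -> |beta|). The strictly convex n-component supplies the grouping
effect (correlated features enter together); the concave m-component supplies
sparsity. The path seeker only ever needs each penalty's *slope*: the derivative
of the per-coordinate penalty with respect to |beta_j|.

Comparator penalties (Lasso, l_1/2, Elastic net, l_1/2 + l_2) are provided behind
the same plugin contract so every method runs through the identical solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

#: smoothing constant inside sqrt(|beta| + EPS) for the l_1/2-type slopes, whose
#: exact derivative diverges at 0; keeps the gradient ratio finite.
EPS_L12 = 1e-8

#: floor on the combined CHR slope; the n-component's slope is exactly 0 at
#: beta = 0, so gamma = 0 would otherwise yield a zero slope there.
SLOPE_FLOOR = 1e-12


@dataclass(frozen=True)
class ChrHyperparams:
    """CHR hyperparameters: a, b in (0,1) and mixing weight gamma in [0,1].

    gamma = lambda_1 / (lambda_1 + lambda_2) weights the sparsity component m
    against the grouping component n.
    """

    a: float
    b: float
    gamma: float

    def __post_init__(self):
        if not (0.0 < self.a < 1.0):
            raise ValueError(f"a must lie in (0, 1), got {self.a}")
        if not (0.0 < self.b < 1.0):
            raise ValueError(f"b must lie in (0, 1), got {self.b}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.gamma])


@dataclass(frozen=True)
class PenaltyPlugin:
    """Per-coordinate penalty with its derivative w.r.t. |beta|.

    ``value`` and ``slope`` are vectorised over beta. The contract demands
    value(0) = 0, sign symmetry, and strictly positive slope for finite beta
    (so the gradient ratio of the path seeker is defined everywhere).
    """

    name: str
    value: Callable[[np.ndarray], np.ndarray]
    slope: Callable[[np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# CHR pair


def _check_a(a: float) -> None:
    if not (0.0 < a < 1.0):
        raise ValueError(f"CHR parameter must lie in (0, 1), got {a}")


def chr_m(beta, a: float):
    """Sparsity component m(beta; a); concave increasing in |beta|."""
    _check_a(a)
    beta = np.abs(np.asarray(beta, dtype=float))
    c = (1.0 - a) / a
    return np.sqrt((2.0 / (a * (a + 1.0))) * beta + c * c) - c


def chr_n(beta, b: float):
    """Grouping component n(beta; b); convex increasing in |beta|."""
    _check_a(b)
    beta = np.abs(np.asarray(beta, dtype=float))
    c = (1.0 - b) / b
    return np.sqrt((2.0 / (b * (b + 1.0))) * beta * beta + c * c) - c


def chr_m_slope(beta, a: float):
    """d m / d|beta|. At beta = 0 this equals 1/(1 - a^2)."""
    _check_a(a)
    beta = np.abs(np.asarray(beta, dtype=float))
    c = (1.0 - a) / a
    k = 2.0 / (a * (a + 1.0))
    return (k / 2.0) / np.sqrt(k * beta + c * c)


def chr_n_slope(beta, b: float):
    """d n / d|beta|; vanishes at beta = 0 (ridge-like)."""
    _check_a(b)
    beta = np.abs(np.asarray(beta, dtype=float))
    c = (1.0 - b) / b
    k = 2.0 / (b * (b + 1.0))
    return k * beta / np.sqrt(k * beta * beta + c * c)


def chr_value(beta, params: ChrHyperparams):
    return params.gamma * chr_m(beta, params.a) + (1.0 - params.gamma) * chr_n(
        beta, params.b
    )


def chr_slope(beta, params: ChrHyperparams):
    """Combined slope gamma*m' + (1-gamma)*n', floored away from zero."""
    s = params.gamma * chr_m_slope(beta, params.a) + (
        1.0 - params.gamma
    ) * chr_n_slope(beta, params.b)
    return np.maximum(s, SLOPE_FLOOR)


def chr_plugin(params: ChrHyperparams) -> PenaltyPlugin:
    return PenaltyPlugin(
        name="chr",
        value=lambda beta: chr_value(beta, params),
        slope=lambda beta: chr_slope(beta, params),
    )


# ---------------------------------------------------------------------------
# Comparator plugins


def _lasso() -> PenaltyPlugin:
    return PenaltyPlugin(
        name="lasso",
        value=lambda b: np.abs(np.asarray(b, dtype=float)),
        slope=lambda b: np.ones_like(np.asarray(b, dtype=float)),
    )


def _l12() -> PenaltyPlugin:
    def value(b):
        return np.sqrt(np.abs(np.asarray(b, dtype=float)) + EPS_L12) - np.sqrt(EPS_L12)

    def slope(b):
        return 0.5 / np.sqrt(np.abs(np.asarray(b, dtype=float)) + EPS_L12)

    return PenaltyPlugin(name="l12", value=value, slope=slope)


def _enet(alpha: float) -> PenaltyPlugin:
    def value(b):
        b = np.abs(np.asarray(b, dtype=float))
        return alpha * b + (1.0 - alpha) * b * b

    def slope(b):
        b = np.abs(np.asarray(b, dtype=float))
        return alpha + (1.0 - alpha) * 2.0 * b

    return PenaltyPlugin(name="enet", value=value, slope=slope)


def _l12l2(alpha: float) -> PenaltyPlugin:
    def value(b):
        b = np.abs(np.asarray(b, dtype=float))
        return alpha * (np.sqrt(b + EPS_L12) - np.sqrt(EPS_L12)) + (1.0 - alpha) * b * b

    def slope(b):
        b = np.abs(np.asarray(b, dtype=float))
        return alpha * 0.5 / np.sqrt(b + EPS_L12) + (1.0 - alpha) * 2.0 * b

    return PenaltyPlugin(name="l12l2", value=value, slope=slope)


PENALTY_NAMES = ("chr", "lasso", "l12", "enet", "l12l2")


def get_plugin(
    name: str,
    hyperparams: ChrHyperparams | None = None,
    alpha: float = 0.5,
) -> PenaltyPlugin:
    """Look up a penalty plugin by name.

    ``hyperparams`` is required for "chr"; ``alpha`` is the mixing weight of the
    elastic-net-family comparators (must be > 0 so the slope stays positive at 0).
    """
    if name == "chr":
        if hyperparams is None:
            raise ValueError("the chr penalty requires ChrHyperparams")
        return chr_plugin(hyperparams)
    if name == "lasso":
        return _lasso()
    if name == "l12":
        return _l12()
    if name in ("enet", "l12l2"):
        if not (0.0 < alpha <= 1.0):
            raise ValueError("mixing weight alpha must lie in (0, 1]")
        return _enet(alpha) if name == "enet" else _l12l2(alpha)
    raise ValueError(f"unknown penalty {name!r}; available: {', '.join(PENALTY_NAMES)}")


def comparator_plugins(alpha: float = 0.5) -> list[PenaltyPlugin]:
    """The four comparator penalties behind the common plugin contract."""
    return [_lasso(), _l12(), _enet(alpha), _l12l2(alpha)]
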