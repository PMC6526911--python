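"""Gamma-distributed mutation-rate heterogeneity as a mixture of generators.

A global rescaling of the generator would speed up drift together with
mutation, which is wrong for the boundary mutation model: only mutation
rates vary across sites.  Heterogeneity is therefore a mixture over ``K``
equal-probability categories with rate modifiers ``r_k`` applied to the
mutation part only,

    Q_k = r_k * QM + QD,

and the site likelihood is the unweighted mean over categories.  The
``r_k`` are the *means* of the K equal-probability slices of a mean-one
Gamma(alpha) distribution (renormalized so the discretized mean is exactly
one).

Each category generator has a distinct stationary distribution and needs
its own eigendecomposition; categories share a single normalization
constant, derived from the probability-weighted mean generator, so that
branch lengths keep one meaning across categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .mutation import MutationModel
from .ratematrix import (
    RateMatrixSet,
    stationary_closed_form,
    stationary_numeric,
)
from .statespace import StateSpace

__all__ = [
    "GammaMixture",
    "discretize_gamma",
    "category_matrices",
    "mixture_site_likelihood",
    "ALPHA_FLOOR",
    "ALPHA_HOMOGENEOUS",
]

ALPHA_FLOOR = 0.01          # below this the discretization is numerically fragile
ALPHA_HOMOGENEOUS = 1e6     # at or above this the mixture collapses to one rate


@dataclass(frozen=True)
class GammaMixture:
    """K-category discretization of mean-one Gamma(alpha) rate heterogeneity."""

    alpha: float
    K: int
    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.weights @ self.rates) - 1.0) > 1e-10:
            raise ValueError("category rates must average to 1")
        if self.K > 1 and np.any(np.diff(self.rates) <= 0):
            raise ValueError("category rates must be strictly increasing")

    @classmethod
    def homogeneous(cls) -> "GammaMixture":
        return cls(np.inf, 1, np.array([1.0]), np.array([1.0]))


def discretize_gamma(alpha: float, K: int) -> GammaMixture:
    """Equal-probability categories of Gamma(alpha, mean 1); rates are slice means.

    The mean of slice ``(x_k, x_{k+1}]`` of a Gamma with shape ``a`` and rate
    ``a`` is ``K * (P(a+1, a x_{k+1}) - P(a+1, a x_k))`` with ``P`` the
    regularized lower incomplete gamma function.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not np.isfinite(alpha) or alpha >= ALPHA_HOMOGENEOUS:
        # degenerate limit: all categories at rate one
        return _degenerate_mixture(alpha, K)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if alpha < ALPHA_FLOOR:
        raise ValueError(f"alpha below numerical floor {ALPHA_FLOOR}")
    if K == 1:
        return GammaMixture(alpha, 1, np.array([1.0]), np.array([1.0]))
    edges = stats.gamma.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    cum = special.gammainc(alpha + 1.0, alpha * edges)
    cum = np.concatenate([[0.0], cum, [1.0]])
    rates = K * np.diff(cum)
    rates = rates / (rates.mean())  # absorb quadrature error: mean exactly 1
    return GammaMixture(alpha, K, rates, np.full(K, 1.0 / K))


def _degenerate_mixture(alpha: float, K: int) -> GammaMixture:
    # All categories at rate one; bypass the strict-monotonicity invariant.
    obj = object.__new__(GammaMixture)
    object.__setattr__(obj, "alpha", alpha)
    object.__setattr__(obj, "K", K)
    object.__setattr__(obj, "rates", np.ones(K))
    object.__setattr__(obj, "weights", np.full(K, 1.0 / K))
    return obj


def category_matrices(
    QM: np.ndarray,
    QD: np.ndarray,
    mix: GammaMixture,
    space: StateSpace | None = None,
    model: MutationModel | None = None,
) -> list[RateMatrixSet]:
    """Per-category generators ``Q_k = r_k QM + QD`` with one shared scale.

    The shared normalization constant comes from the weighted-average
    generator (which equals ``QM + QD`` because the rates average to one).
    When ``space`` and ``model`` are given, per-category stationary
    distributions use the reversible closed form (scaling the mutation part
    by ``r_k`` is equivalent to scaling the magnitude); otherwise they are
    solved numerically.
    """
    mean_r = float(mix.weights @ mix.rates)
    Qbar = mean_r * QM + QD
    stat_bar = stationary_numeric(Qbar)
    scale = float(-(stat_bar * np.diag(Qbar)).sum())
    out = []
    for r in mix.rates:
        Qk = r * QM + QD
        if space is not None and model is not None:
            stat = stationary_closed_form(space, model.with_magnitude(model.magnitude * r))
        else:
            stat = stationary_numeric(Qk)
        out.append(
            RateMatrixSet(
                QM=r * QM / scale, QD=QD / scale, Q=Qk / scale,
                stationary=stat, scale=scale,
            )
        )
    return out


def mixture_site_likelihood(per_category_likelihoods) -> float:
    """Site likelihood: unweighted mean over the K category likelihoods."""
    vals = np.asarray(per_category_likelihoods, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one category likelihood")
    return float(vals.mean())
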