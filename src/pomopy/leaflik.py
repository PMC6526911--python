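"""Leaf conditional likelihoods over PoMo states from observed allele counts.

At a leaf we observe ``M`` sampled alleles with counts per nucleotide; the
model state is an allele-frequency bin over ``N`` virtual individuals, so
the observation must be mapped to a likelihood vector over states.  Three
strategies are provided:

``sampled``
    Binomially draw ``N`` alleles from the observed frequencies and set
    likelihood one at the resulting state (a random, seeded hard
    assignment).

``weighted binomial`` (default downstream)
    Likelihood of state ``{i a | (N-i) b}`` is the binomial probability of
    drawing the observed sample ``{j a | (M-j) b}`` with success
    probability ``i/N`` (sampling with replacement).

``weighted hypergeometric``
    As above but sampling without replacement from the ``N`` bins,
    ``C(i,j) C(N-i, M-j) / C(N, M)``; requires ``M <= N`` and reduces to an
    indicator when ``M = N``.

Monomorphic states are handled as the natural ``i in {0, N}`` limits of the
formulas.  A missing observation initializes all states to one.  At most
two segregating alleles can be represented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, hypergeom

from .statespace import StateSpace

__all__ = [
    "SiteObservation",
    "UnrepresentableObservationError",
    "init_sampled",
    "init_weighted_binomial",
    "init_weighted_hypergeometric",
    "leaf_likelihood",
    "STRATEGIES",
]


class UnrepresentableObservationError(ValueError):
    """Observation cannot be mapped onto the two-allele PoMo state space."""


@dataclass
class SiteObservation:
    """Allele counts observed for one population at one site."""

    counts: np.ndarray
    missing: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("allele counts must be nonnegative")

    @property
    def M(self) -> int:
        """Total number of sampled alleles."""
        return int(self.counts.sum())

    def segregating(self) -> np.ndarray:
        """Indices of alleles with nonzero counts."""
        return np.nonzero(self.counts)[0]


def _observed_pair(obs: SiteObservation, space: StateSpace):
    """Return (allele index c, allele index d or None, count j of c)."""
    nz = obs.segregating()
    if len(nz) > 2:
        raise UnrepresentableObservationError(
            f"{len(nz)} segregating alleles observed; PoMo states hold at most 2"
        )
    if len(nz) == 1:
        return int(nz[0]), None, int(obs.counts[nz[0]])
    c, d = int(nz[0]), int(nz[1])
    return c, d, int(obs.counts[c])


def init_sampled(
    obs: SiteObservation, space: StateSpace, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Hard assignment: binomially sample ``N`` alleles from the observation."""
    S = space.n_states
    if obs.missing or obs.M == 0:
        if not obs.missing and obs.M == 0:
            import warnings

            warnings.warn("observation with M=0 treated as missing", stacklevel=2)
        return np.ones(S)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    c, d, j = _observed_pair(obs, space)
    L = np.zeros(S)
    syms = space.alphabet.symbols
    if d is None:
        L[space.monomorphic_index(syms[c])] = 1.0
        return L
    i = int(rng.binomial(space.N, j / obs.M))
    L[space.polymorphic_index(syms[c], syms[d], i)] = 1.0
    return L


def _pairwise_values(obs: SiteObservation, space: StateSpace, pmf) -> np.ndarray:
    """Shared scaffold for the two weighted strategies.

    ``pmf(j, M, i)`` gives the probability of observing ``j`` copies of the
    first allele out of ``M`` given ``i`` of ``N`` bins carry it.
    """
    S = space.n_states
    if obs.missing or obs.M == 0:
        return np.ones(S)
    c, d, j = _observed_pair(obs, space)
    syms = space.alphabet.symbols
    N = space.N
    M = obs.M
    L = np.zeros(S)
    i = np.arange(1, N)
    if d is None:
        # Monomorphic observation of allele c: the matching monomorphic state
        # (i = N) and, for every partner allele b, the polymorphic column with
        # i copies of c.
        L[space.monomorphic_index(syms[c])] = pmf(j, M, N)
        for b in range(space.alphabet.size):
            if b == c:
                continue
            block = space.pair_block(syms[c], syms[b])
            ii = i if c < b else N - i  # i counts the pair's first allele
            L[block] = pmf(j, M, ii)
        return L
    # Polymorphic observation {j c | (M-j) d}: only states over the same pair,
    # including both monomorphic boundaries (i = N and i = 0).
    block = space.pair_block(syms[c], syms[d])
    L[block] = pmf(j, M, i)  # c < d by construction of _observed_pair
    L[space.monomorphic_index(syms[c])] = pmf(j, M, N)
    L[space.monomorphic_index(syms[d])] = pmf(j, M, 0)
    return L


def init_weighted_binomial(obs: SiteObservation, space: StateSpace) -> np.ndarray:
    """Binomial-sampling likelihoods ``C(M,j) (i/N)^j ((N-i)/N)^(M-j)``."""
    N = space.N

    def pmf(j, M, i):
        return binom.pmf(j, M, np.asarray(i) / N)

    return _pairwise_values(obs, space, pmf)


def init_weighted_hypergeometric(obs: SiteObservation, space: StateSpace) -> np.ndarray:
    """Hypergeometric likelihoods ``C(i,j) C(N-i, M-j) / C(N, M)``; needs M <= N."""
    if not obs.missing and obs.M > space.N:
        raise ValueError(
            f"weighted hypergeometric sampling is undefined for M={obs.M} > N={space.N}"
        )
    N = space.N

    def pmf(j, M, i):
        return hypergeom.pmf(j, N, np.asarray(i), M)

    return _pairwise_values(obs, space, pmf)


STRATEGIES = {
    "sampled": init_sampled,
    "wbinomial": init_weighted_binomial,
    "whypergeometric": init_weighted_hypergeometric,
}


def leaf_likelihood(
    obs: SiteObservation,
    space: StateSpace,
    strategy: str = "wbinomial",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Dispatch to a named strategy (``sampled`` needs an ``rng``)."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}")
    if strategy == "sampled":
        return init_sampled(obs, space, rng if rng is not None else 0)
    return STRATEGIES[strategy](obs, space)
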