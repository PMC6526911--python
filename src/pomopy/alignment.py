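"""Allele-count alignments with site-pattern compression.

A counts alignment stores, for every site and population, the vector of
observed allele counts (one entry per alphabet symbol).  Sites are treated
as independent, so the likelihood only depends on the multiset of site
patterns; :meth:`CountsAlignment.compressed` returns unique patterns with
multiplicities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .leaflik import SiteObservation
from .statespace import DNA, Alphabet

__all__ = ["CountsAlignment"]


@dataclass
class CountsAlignment:
    """Per-population, per-site allele counts.

    ``counts`` has shape ``(n_sites, n_populations, |A|)``.  A row of all
    zeros for a population marks a missing observation at that site.
    """

    populations: list[str]
    counts: np.ndarray
    alphabet: Alphabet = field(default_factory=lambda: DNA)
    chrom: list[str] | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (n_sites, n_populations, |A|)")
        n_sites, n_pop, n_sym = self.counts.shape
        if n_pop != len(self.populations):
            raise ValueError("population axis does not match population names")
        if n_sym != self.alphabet.size:
            raise ValueError("allele axis does not match the alphabet")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("population names must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def observation(self, site: int, population: str | int) -> SiteObservation:
        p = (
            population
            if isinstance(population, int)
            else self.populations.index(population)
        )
        row = self.counts[site, p]
        return SiteObservation(row, missing=bool(row.sum() == 0))

    def compressed(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns and their multiplicities.

        Returns ``(patterns, weights)`` with ``patterns`` of shape
        ``(n_patterns, n_populations, |A|)``; ``weights`` sums to
        ``n_sites``.  The pattern key is the full tuple of per-population
        count vectors.
        """
        flat = np.ascontiguousarray(self.counts.reshape(self.n_sites, -1))
        patterns, weights = np.unique(flat, axis=0, return_counts=True)
        return (
            patterns.reshape(-1, self.n_populations, self.alphabet.size),
            weights.astype(float),
        )

    def empirical_frequencies(self) -> np.ndarray:
        """Pooled allele frequencies across all sites and populations."""
        tot = self.counts.sum(axis=(0, 1)).astype(float)
        s = tot.sum()
        if s == 0:
            raise ValueError("alignment contains no observed alleles")
        return tot / s

    def polymorphic_fraction(self) -> float:
        """Fraction of non-missing observations with more than one allele."""
        nonzero = (self.counts > 0).sum(axis=2)
        observed = nonzero > 0
        if not observed.any():
            raise ValueError("alignment contains no observed alleles")
        return float((nonzero > 1).sum() / observed.sum())

    def resample(self, rng: np.random.Generator) -> "CountsAlignment":
        """Nonparametric bootstrap resample of sites (with replacement)."""
        idx = rng.integers(0, self.n_sites, size=self.n_sites)
        return CountsAlignment(
            list(self.populations), self.counts[idx], self.alphabet
        )

    def subset(self, sites) -> "CountsAlignment":
        return CountsAlignment(
            list(self.populations), self.counts[np.asarray(sites)], self.alphabet
        )
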