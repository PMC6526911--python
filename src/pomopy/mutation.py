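"""Reversible mutation models (JC, HKY, GTR) feeding the boundary mutation model.

A mutation model supplies the rates ``q_ab`` of the underlying nucleotide
process.  We use the standard reversible parameterization

    q_ab = mu * rho_ab * pi_b,   rho_ab = rho_ba,

with stationary frequencies ``pi``, symmetric exchangeabilities ``rho`` and
an overall magnitude ``mu``.  For HKY, ``rho_ab = kappa`` on transitions
(A<->G, C<->T) and 1 on transversions.  Reversibility
``pi_a q_ab = pi_b q_ba`` holds by construction.

Within the boundary mutation model, mutations act only from monomorphic
states, so ``mu`` directly controls the stationary level of polymorphism;
it is usually set by calibrating to a target heterozygosity (see
:func:`pomopy.ratematrix.calibrate_heterozygosity`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .statespace import DNA, Alphabet

__all__ = ["MutationModel", "mutation_rate"]

# Purine/pyrimidine transitions for the nucleotide alphabet.
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class MutationModel:
    """Reversible mutation model ``q_ab = mu * rho_ab * pi_b``."""

    name: str
    pi: np.ndarray
    exchangeabilities: np.ndarray
    magnitude: float = 1.0
    kappa: float | None = None
    alphabet: Alphabet = field(default_factory=lambda: DNA)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        n = self.alphabet.size
        if self.pi.shape != (n,):
            raise ValueError(f"pi must have length {n}")
        if np.any(self.pi <= 0):
            raise ValueError("stationary frequencies must be strictly positive")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("stationary frequencies must sum to 1")
        if self.exchangeabilities.shape != (n, n):
            raise ValueError("exchangeability matrix has wrong shape")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeabilities must be symmetric")
        if self.magnitude <= 0:
            raise ValueError("mutation magnitude must be positive")

    # -- constructors -------------------------------------------------------

    @classmethod
    def jc(cls, magnitude: float = 1.0, alphabet: Alphabet = DNA) -> "MutationModel":
        """Jukes-Cantor: uniform frequencies, equal exchangeabilities."""
        n = alphabet.size
        rho = np.ones((n, n)) - np.eye(n)
        return cls("JC", np.full(n, 1.0 / n), rho, magnitude, alphabet=alphabet)

    @classmethod
    def hky(cls, kappa: float, pi, magnitude: float = 1.0) -> "MutationModel":
        """HKY: transition/transversion ratio ``kappa``, frequencies ``pi``."""
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        alphabet = DNA
        n = alphabet.size
        rho = np.ones((n, n)) - np.eye(n)
        for a, b in _TRANSITIONS:
            rho[alphabet.index(a), alphabet.index(b)] = kappa
        return cls("HKY", pi, rho, magnitude, kappa=kappa)

    @classmethod
    def gtr(cls, rates, pi, magnitude: float = 1.0) -> "MutationModel":
        """GTR with six exchangeabilities in order AC, AG, AT, CG, CT, GT."""
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (6,) or np.any(rates <= 0):
            raise ValueError("GTR needs six positive exchangeabilities")
        rho = np.zeros((4, 4))
        for (i, j), r in zip([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], rates):
            rho[i, j] = rho[j, i] = r
        return cls("GTR", pi, rho, magnitude)

    @classmethod
    def custom(cls, exchangeabilities, pi, magnitude: float = 1.0,
               alphabet: Alphabet = DNA) -> "MutationModel":
        return cls("custom", pi, exchangeabilities, magnitude, alphabet=alphabet)

    # -- rates ---------------------------------------------------------------

    def rate(self, a: str, b: str) -> float:
        """Mutation rate ``q_ab`` for distinct alleles ``a != b``."""
        if a == b:
            raise ValueError("mutation rate requires two distinct alleles")
        ia, ib = self.alphabet.index(a), self.alphabet.index(b)
        return self.magnitude * self.exchangeabilities[ia, ib] * self.pi[ib]

    def rate_matrix(self) -> np.ndarray:
        """Matrix of ``q_ab`` (off-diagonal only; diagonal zero)."""
        Q = self.magnitude * self.exchangeabilities * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        return Q

    def with_magnitude(self, magnitude: float) -> "MutationModel":
        return replace(self, magnitude=float(magnitude))

    def with_kappa(self, kappa: float) -> "MutationModel":
        if self.name != "HKY":
            raise ValueError("with_kappa only applies to HKY models")
        return MutationModel.hky(kappa, self.pi.copy(), self.magnitude)

    def with_pi(self, pi) -> "MutationModel":
        return replace(self, pi=np.asarray(pi, dtype=float))

    @property
    def gtr_rates(self) -> np.ndarray:
        """Six exchangeabilities in order AC, AG, AT, CG, CT, GT."""
        r = self.exchangeabilities
        return np.array([r[0, 1], r[0, 2], r[0, 3], r[1, 2], r[1, 3], r[2, 3]])


def mutation_rate(model: MutationModel, a: str, b: str) -> float:
    """Rate ``q_ab`` of mutations from allele ``a`` to allele ``b``."""
    return model.rate(a, b)
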