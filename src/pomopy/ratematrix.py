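"""Boundary-mutation-model rate matrices over the PoMo state space.

The generator decomposes as ``Q = QM + QD``: mutations act only out of
monomorphic ("boundary") states,

    (QM){a} -> {(N-1)a | 1b} = q_ab,

while genetic drift follows the continuous-time Moran process and moves
between neighbouring allele-frequency states only,

    (QD){i a | (N-i) b} -> {(i +/- 1) a | ...} = i (N - i) / N,

including the steps onto the monomorphic boundaries.  Diagonals are set so
that rows sum to zero.

For a reversible mutation model the stationary distribution has a closed
form: monomorphic mass proportional to ``pi_a``, polymorphic mass of
``{i a | (N-i) b}`` proportional to ``mu * rho_ab * pi_a * pi_b * N / (i (N-i))``.
Both this closed form and a generic numeric null-left-eigenvector solve are
provided; they are cross-checked in the test suite.

Branch lengths are measured in expected events (mutations plus drift
steps) per site: ``assemble_rate_matrix(..., normalize=True)`` rescales the
generator so the expected total event rate at stationarity is one.  The
applied scale is exposed on the result for unit conversions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .mutation import MutationModel
from .statespace import StateSpace

__all__ = [
    "RateMatrixSet",
    "build_mutation_matrix",
    "build_drift_matrix",
    "assemble_rate_matrix",
    "stationary_closed_form",
    "stationary_numeric",
    "polymorphic_mass",
    "calibrate_heterozygosity",
    "expected_substitution_rate",
    "events_per_substitution",
    "transition_probabilities",
    "SpectralDecomposition",
    "HETEROZYGOSITY_VALIDITY_BOUND",
]

#: Above this stationary polymorphic mass the boundary-mutation approximation
#: (no mutations while polymorphic) degrades.
HETEROZYGOSITY_VALIDITY_BOUND = 0.1


def build_mutation_matrix(space: StateSpace, model: MutationModel) -> np.ndarray:
    """Mutation part ``QM``: rates out of monomorphic states only."""
    if model.alphabet.symbols != space.alphabet.symbols:
        raise ValueError("state space and mutation model use different alphabets")
    S = space.n_states
    QM = np.zeros((S, S))
    for a in space.alphabet.symbols:
        ia = space.monomorphic_index(a)
        for b in space.alphabet.symbols:
            if a == b:
                continue
            # {a} -> {(N-1) a | 1 b}: the new allele b enters at frequency 1/N.
            j = space.polymorphic_index(a, b, space.N - 1)
            QM[ia, j] = model.rate(a, b)
    np.fill_diagonal(QM, -QM.sum(axis=1))
    return QM


def build_drift_matrix(space: StateSpace) -> np.ndarray:
    """Drift part ``QD``: Moran rates ``i(N-i)/N`` between neighbour states."""
    S = space.n_states
    N = space.N
    QD = np.zeros((S, S))
    for a, b in space.pairs:
        for i in range(1, N):
            s = space.polymorphic_index(a, b, i)
            rate = i * (N - i) / N
            QD[s, space.polymorphic_index(a, b, i + 1)] += rate
            QD[s, space.polymorphic_index(a, b, i - 1)] += rate
    np.fill_diagonal(QD, QD.diagonal() - QD.sum(axis=1))
    return QD


@dataclass
class RateMatrixSet:
    """Assembled generator with its stationary distribution and scale.

    ``scale`` is the factor the raw ``QM + QD`` was divided by; 1.0 when
    ``normalize=False``.  ``Q = QM + QD`` holds for the stored (scaled)
    components.
    """

    QM: np.ndarray
    QD: np.ndarray
    Q: np.ndarray
    stationary: np.ndarray
    scale: float

    _spectral: "SpectralDecomposition | None" = None

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def spectral(self) -> "SpectralDecomposition":
        if self._spectral is None:
            self._spectral = SpectralDecomposition(self.Q, self.stationary)
        return self._spectral


def stationary_numeric(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution as the normalized null left-eigenvector.

    Falls back to solving the augmented linear system if the eigenvector
    closest to eigenvalue zero is numerically unusable.
    """
    w, v = scipy.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    s = pi.sum()
    if abs(s) < 1e-12 or np.max(np.abs(np.imag(v[:, k]))) > 1e-8:
        # Augmented system: Q^T pi = 0 with sum(pi) = 1.
        S = Q.shape[0]
        A = np.vstack([Q.T, np.ones((1, S))])
        b = np.zeros(S + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        s = pi.sum()
    if abs(s) < 1e-12:
        raise np.linalg.LinAlgError("stationary solve failed: null vector sums to 0")
    pi = pi / s
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def stationary_closed_form(space: StateSpace, model: MutationModel) -> np.ndarray:
    """Closed-form stationary distribution for a reversible mutation model."""
    S = space.n_states
    m = np.zeros(S)
    idx = {a: space.monomorphic_index(a) for a in space.alphabet.symbols}
    for a in space.alphabet.symbols:
        m[idx[a]] = model.pi[space.alphabet.index(a)]
    N = space.N
    for a, b in space.pairs:
        ia, ib = space.alphabet.index(a), space.alphabet.index(b)
        base = (
            model.magnitude
            * model.exchangeabilities[ia, ib]
            * model.pi[ia]
            * model.pi[ib]
        )
        block = space.pair_block(a, b)
        i = np.arange(1, N)
        m[block] = base * N / (i * (N - i))
    return m / m.sum()


def assemble_rate_matrix(
    QM: np.ndarray, QD: np.ndarray, normalize: bool = True
) -> RateMatrixSet:
    """Assemble ``Q = QM + QD`` and solve for its stationary distribution.

    With ``normalize=True`` the generator (and its parts) are divided by the
    expected event rate at stationarity, ``-sum_s stationary_s Q_ss``, so a
    branch of length 1 carries one expected event per site.
    """
    if QM.shape != QD.shape:
        raise ValueError("QM and QD must be conformable")
    Q = QM + QD
    stationary = stationary_numeric(Q)
    scale = 1.0
    if normalize:
        scale = float(-(stationary * np.diag(Q)).sum())
        if scale <= 0:
            raise np.linalg.LinAlgError("non-positive event rate; cannot normalize")
        Q = Q / scale
        QM = QM / scale
        QD = QD / scale
    return RateMatrixSet(QM=QM, QD=QD, Q=Q, stationary=stationary, scale=scale)


def polymorphic_mass(space: StateSpace, model: MutationModel) -> float:
    """Stationary probability of being in any polymorphic state."""
    pi = stationary_closed_form(space, model)
    return float(pi[space.polymorphic_mask].sum())


def expected_substitution_rate(space: StateSpace, model: MutationModel) -> float:
    """Stationary substitution rate in raw (unnormalized) time units.

    Mutations arise from monomorphic states at total rate
    ``sum_a pi^st_a sum_b q_ab`` and a neutral single mutant fixes with
    probability ``1/N`` under the Moran process, so the expected number of
    substitutions per site per raw time unit is that flux divided by ``N``.
    """
    stat = stationary_closed_form(space, model)
    rate = 0.0
    for a in space.alphabet.symbols:
        ia = space.monomorphic_index(a)
        out = sum(model.rate(a, b) for b in space.alphabet.symbols if b != a)
        rate += stat[ia] * out
    return rate / space.N


def events_per_substitution(space: StateSpace, model: MutationModel) -> float:
    """Conversion factor: normalized-event branch units per substitution.

    Multiply a branch length in expected substitutions per site by this
    factor to express it in the normalized event units used throughout
    (one expected mutation-plus-drift event per site per unit length).
    """
    QM = build_mutation_matrix(space, model)
    QD = build_drift_matrix(space)
    stat = stationary_closed_form(space, model)
    event_rate = float(-(stat * np.diag(QM + QD)).sum())
    return event_rate / expected_substitution_rate(space, model)


def calibrate_heterozygosity(
    model: MutationModel, space: StateSpace, theta: float
) -> MutationModel:
    """Set the mutation magnitude so the stationary polymorphic mass is ``theta``.

    The polymorphic mass is strictly increasing in the magnitude ``mu`` (it
    equals ``mu*S / (1 + mu*S)`` for a model-dependent constant ``S``), so a
    bracketed 1-D root solve is exact.  Emits a warning above the model's
    validity bound of 0.1.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie strictly between 0 and 1")
    if theta > HETEROZYGOSITY_VALIDITY_BOUND:
        warnings.warn(
            f"theta={theta} exceeds {HETEROZYGOSITY_VALIDITY_BOUND}; the "
            "boundary mutation model assumes rare polymorphism",
            stacklevel=2,
        )

    def mass(mu: float) -> float:
        return polymorphic_mass(space, model.with_magnitude(mu))

    lo, hi = 1e-12, 1.0
    while mass(hi) < theta:
        hi *= 10.0
        if hi > 1e12:
            raise ValueError(
                f"theta={theta} unattainable; attainable range is (0, 1) but "
                "requires unreasonable mutation magnitudes"
            )
    mu = scipy.optimize.brentq(lambda m: mass(m) - theta, lo, hi, xtol=1e-16, rtol=1e-14)
    return model.with_magnitude(mu)


class SpectralDecomposition:
    """Eigendecomposition of a reversible generator for fast ``exp(Qt)``.

    A reversible ``Q`` is similar to a symmetric matrix via
    ``D Q D^-1`` with ``D = diag(sqrt(stationary))``; ``exp(Qt)`` then
    follows from a single symmetric eigendecomposition.
    """

    #: probabilities below this (in magnitude) are clamped to zero
    CLAMP = 1e-12

    #: smallest stationary entry for which the symmetric route is accurate;
    #: the rounding error grows like eps * sqrt(max/min of the stationary
    #: distribution), so below this we fall back to Pade scaling-and-squaring
    MIN_STATIONARY = 1e-8

    def __init__(self, Q: np.ndarray, stationary: np.ndarray):
        self._Q = Q
        self._symmetric_ok = bool(stationary.min() >= self.MIN_STATIONARY)
        if self._symmetric_ok:
            d = np.sqrt(stationary)
            sym = Q * (d[:, None] / d[None, :])
            sym = 0.5 * (sym + sym.T)
            w, V = scipy.linalg.eigh(sym)
            self.eigenvalues = w
            self._left = V / d[:, None]      # diag(1/d) @ V
            self._right = V.T * d[None, :]   # V.T @ diag(d)
        else:
            self.eigenvalues = None

    def expm(self, t: float) -> np.ndarray:
        """Transition probability matrix ``exp(Qt)``."""
        if self._symmetric_ok:
            P = (self._left * np.exp(self.eigenvalues * t)) @ self._right
        else:
            P = scipy.linalg.expm(self._Q * t)
        np.clip(P, 0.0, None, out=P)
        return P


def transition_probabilities(rates: RateMatrixSet, t: float) -> np.ndarray:
    """CTMC transition probabilities ``exp(Qt)`` for branch length ``t >= 0``."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if t == 0:
        return np.eye(rates.n_states)
    return rates.spectral().expm(t)
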