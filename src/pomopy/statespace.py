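"""PoMo state space: monomorphic and polymorphic population states.

A population of ``N`` virtual individuals is either monomorphic for one
allele, written ``{a}``, or polymorphic for an unordered pair of alleles
with counts ``i`` and ``N - i``, written ``{i a | (N-i) b}``.  ``N`` is a
discretization parameter (the number of allele-frequency bins), not an
effective population size.

The total number of states is ``|A| + C(|A|, 2) * (N - 1)``.

State ordering is frozen for serialization: the ``|A|`` monomorphic states
come first in alphabet order, followed by one block per unordered allele
pair (pairs in lexicographic order), each block enumerating ``i = 1..N-1``
where ``i`` counts the pair's first allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["Alphabet", "DNA", "State", "StateSpace", "build_state_space"]


@dataclass(frozen=True)
class Alphabet:
    """Ordered allele alphabet, by default the four nucleotides."""

    symbols: tuple[str, ...] = ("A", "C", "G", "T")

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.symbols)


DNA = Alphabet()


@dataclass(frozen=True)
class State:
    """One PoMo state.

    Monomorphic states carry ``second=None`` and ``count=N``; polymorphic
    states carry the ordered pair ``(first, second)`` and ``count=i``, the
    number of virtual individuals with the first allele.
    """

    first: str
    second: str | None
    count: int

    @property
    def is_polymorphic(self) -> bool:
        return self.second is not None

    def __str__(self) -> str:
        if self.second is None:
            return "{%s}" % self.first
        return "{%d%s|%s}" % (self.count, self.first, self.second)


class StateSpace:
    """Enumeration and indexing of PoMo states for a given ``N`` and alphabet."""

    def __init__(self, N: int, alphabet: Alphabet = DNA):
        if N < 2:
            raise ValueError(f"virtual population size N must be >= 2, got {N}")
        self.N = int(N)
        self.alphabet = alphabet
        syms = alphabet.symbols
        states: list[State] = [State(a, None, self.N) for a in syms]
        self._pairs: list[tuple[str, str]] = list(combinations(syms, 2))
        for a, b in self._pairs:
            for i in range(1, self.N):
                states.append(State(a, b, i))
        self.states: tuple[State, ...] = tuple(states)
        self._index: dict[tuple[str, str | None, int], int] = {
            (s.first, s.second, s.count): k for k, s in enumerate(states)
        }
        # Boolean mask over states: True on polymorphic states.
        self.polymorphic_mask = np.zeros(len(states), dtype=bool)
        self.polymorphic_mask[alphabet.size :] = True

    @property
    def n_states(self) -> int:
        return len(self.states)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """Unordered allele pairs in block order."""
        return list(self._pairs)

    def monomorphic_index(self, a: str) -> int:
        return self.alphabet.index(a)

    def polymorphic_index(self, a: str, b: str, i: int) -> int:
        """Index of the state with ``i`` copies of ``a`` and ``N - i`` of ``b``.

        The pair may be given in either order; ``i`` always refers to allele
        ``a`` as passed.  ``i = 0`` and ``i = N`` resolve to the monomorphic
        boundaries.
        """
        if i == self.N:
            return self.monomorphic_index(a)
        if i == 0:
            return self.monomorphic_index(b)
        if not 0 < i < self.N:
            raise ValueError(f"count i={i} outside 0..{self.N}")
        ia, ib = self.alphabet.index(a), self.alphabet.index(b)
        if ia == ib:
            raise ValueError("polymorphic state needs two distinct alleles")
        if ia > ib:
            a, b, i = b, a, self.N - i
        key = (a, b, i)
        return self._index[(key[0], key[1], key[2])]

    def index_of(self, state: State) -> int:
        return self._index[(state.first, state.second, state.count)]

    def pair_block(self, a: str, b: str) -> np.ndarray:
        """Indices of the polymorphic states of the (a, b) pair, i = 1..N-1
        counted in the pair's canonical (alphabet) order."""
        ia, ib = self.alphabet.index(a), self.alphabet.index(b)
        if ia > ib:
            a, b = b, a
        block = self._pairs.index((a, b))
        start = self.alphabet.size + block * (self.N - 1)
        return np.arange(start, start + self.N - 1)

    def __repr__(self) -> str:  # pragma: no cover
        return f"StateSpace(N={self.N}, |A|={self.alphabet.size}, states={len(self)})"


def build_state_space(N: int, alphabet: Alphabet = DNA) -> StateSpace:
    """Build the PoMo state space of dimension ``|A| + C(|A|,2)(N-1)``."""
    return StateSpace(N, alphabet)
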