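"""Felsenstein pruning over the PoMo state space with a Gamma mixture.

The engine compresses the alignment to unique site patterns, initializes
per-leaf conditional likelihood matrices with one of the sampling
strategies, and evaluates

    lnL = sum_patterns w * ln( (1/K) sum_k Pr(pattern | Q_k, T) )

by post-order pruning, closing the root with each category's stationary
distribution.  Per-node rescaling with accumulated log factors guards
against underflow.  Spectral decompositions of the K category generators
are cached and reused across branch-length proposals.

For branch-length optimization the engine exposes a single coordinate
sweep built on outer ("up") partial likelihoods, so each 1-D branch
objective costs one transition matrix and one contraction instead of a
full tree pass.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize

from .alignment import CountsAlignment
from .gammamix import GammaMixture, category_matrices
from .leaflik import STRATEGIES, SiteObservation, init_sampled
from .mutation import MutationModel
from .phylotree import PhyloTree
from .ratematrix import build_drift_matrix, build_mutation_matrix
from .statespace import StateSpace

__all__ = ["PruningEngine", "log_likelihood"]

_TINY = 1e-300


class _CategoryModel:
    """Spectral machinery for one mixture category."""

    __slots__ = ("rate", "spectral", "stationary", "Q")

    def __init__(self, rate, spectral, stationary, Q):
        self.rate = rate
        self.spectral = spectral
        self.stationary = stationary
        self.Q = Q


def build_category_models(
    space: StateSpace, model: MutationModel, mix: GammaMixture
) -> list[_CategoryModel]:
    QM = build_mutation_matrix(space, model)
    QD = build_drift_matrix(space)
    sets = category_matrices(QM, QD, mix, space=space, model=model)
    return [_CategoryModel(r, s.spectral(), s.stationary, s.Q) for r, s in zip(mix.rates, sets)]


class PruningEngine:
    """Likelihood engine bound to one tree shape and one alignment."""

    def __init__(
        self,
        tree: PhyloTree,
        aln: CountsAlignment,
        space: StateSpace,
        strategy: str = "wbinomial",
        seed: int = 0,
    ):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}")
        leaf_names = set(tree.leaf_names())
        if leaf_names != set(aln.populations):
            raise ValueError(
                "tree leaves and alignment populations differ: "
                f"{sorted(leaf_names ^ set(aln.populations))}"
            )
        self.space = space
        self.strategy = strategy
        self.patterns, self.weights = aln.compressed()
        self.n_patterns = self.patterns.shape[0]
        self.n_sites = float(self.weights.sum())
        self._rng = np.random.default_rng(seed)
        self._leaf_mats = {
            pop: self._leaf_matrix(p) for p, pop in enumerate(aln.populations)
        }
        self.attach(tree)
        self._cats: list[_CategoryModel] | None = None
        self._cache_key = None

    # -- construction helpers ------------------------------------------------

    def _leaf_matrix(self, pop_index: int) -> np.ndarray:
        """(n_states, n_patterns) conditional likelihoods for one population.

        Observation vectors repeat heavily across patterns, so results are
        cached per distinct count vector (the sampled strategy draws one
        state per *pattern*, in pattern order, for reproducibility).
        """
        S = self.space.n_states
        out = np.empty((S, self.n_patterns))
        cache: dict[bytes, np.ndarray] = {}
        init = STRATEGIES[self.strategy]
        for p in range(self.n_patterns):
            row = self.patterns[p, pop_index]
            key = row.tobytes()
            if self.strategy == "sampled":
                obs = SiteObservation(row, missing=bool(row.sum() == 0))
                out[:, p] = init_sampled(obs, self.space, self._rng)
                continue
            vec = cache.get(key)
            if vec is None:
                obs = SiteObservation(row, missing=bool(row.sum() == 0))
                vec = init(obs, self.space)
                cache[key] = vec
            out[:, p] = vec
        return out

    def attach(self, tree: PhyloTree) -> None:
        """Bind to a tree (same leaf set); reads branch lengths live."""
        self.tree = tree
        self._postorder = list(tree.postorder())
        self._index = {id(n): k for k, n in enumerate(self._postorder)}
        for n in self._postorder:
            if n.is_leaf and n.name not in self._leaf_mats:
                raise ValueError(f"leaf {n.name!r} missing from alignment")

    # -- model binding -------------------------------------------------------

    def set_model(self, model: MutationModel, mix: GammaMixture | None = None) -> None:
        if mix is None:
            mix = GammaMixture.homogeneous()
        key = (
            model.name,
            model.magnitude,
            model.pi.tobytes(),
            model.exchangeabilities.tobytes(),
            mix.K,
            mix.rates.tobytes(),
        )
        if key != self._cache_key:
            self._cats = build_category_models(self.space, model, mix)
            self._cache_key = key
        self.mix = mix

    @property
    def categories(self) -> list[_CategoryModel]:
        if self._cats is None:
            raise RuntimeError("call set_model() before evaluating likelihoods")
        return self._cats

    # -- pruning -------------------------------------------------------------

    def _pmats(self, t: float) -> list[np.ndarray]:
        return [c.spectral.expm(t) for c in self.categories]

    def _downpass(self, keep: bool = False):
        """Post-order conditionals; returns root (D, dlog) per category.

        With ``keep``, stores per-node conditionals for the branch sweep.
        """
        cats = self.categories
        K = len(cats)
        P = self.n_patterns
        D: list = [None] * len(self._postorder)
        dlog: list = [None] * len(self._postorder)
        for k_node, node in enumerate(self._postorder):
            if node.is_leaf:
                D[k_node] = self._leaf_mats[node.name]  # shared across categories
                dlog[k_node] = 0.0
                continue
            acc = None
            lg = np.zeros((K, P))
            for child in node.children:
                ci = self._index[id(child)]
                Pc = self._pmats(child.length)
                Dc = D[ci]
                if acc is None:
                    acc = np.empty((K, self.space.n_states, P))
                    first = True
                else:
                    first = False
                for k in range(K):
                    Dck = Dc if Dc.ndim == 2 else Dc[k]
                    if first:
                        acc[k] = Pc[k] @ Dck
                    else:
                        acc[k] *= Pc[k] @ Dck
                if isinstance(dlog[ci], np.ndarray):
                    lg += dlog[ci]
            m = acc.max(axis=1)
            np.clip(m, _TINY, None, out=m)
            acc /= m[:, None, :]
            lg += np.log(m)
            D[k_node] = acc
            dlog[k_node] = lg
        if keep:
            self._D, self._dlog = D, dlog
        ri = len(self._postorder) - 1
        return D[ri], dlog[ri]

    def _site_loglik(self, Droot, dlog_root) -> np.ndarray:
        cats = self.categories
        K = len(cats)
        logs = np.empty((K, self.n_patterns))
        for k in range(K):
            Dk = Droot if Droot.ndim == 2 else Droot[k]
            site = cats[k].stationary @ Dk
            lg = dlog_root[k] if isinstance(dlog_root, np.ndarray) else 0.0
            logs[k] = np.log(np.clip(site, _TINY, None)) + lg
        mx = logs.max(axis=0)
        mixed = mx + np.log(np.exp(logs - mx).mean(axis=0))
        return mixed

    def log_likelihood(self) -> float:
        Droot, dlog_root = self._downpass()
        site = self._site_loglik(Droot, dlog_root)
        lnl = float(self.weights @ site)
        if not np.isfinite(lnl):
            raise FloatingPointError("non-finite log-likelihood")
        return lnl

    # -- branch-length sweep -------------------------------------------------

    def optimize_branches(
        self,
        bounds: tuple[float, float] = (1e-8, 10.0),
        xtol: float = 1e-3,
    ) -> float:
        """One pre-order coordinate sweep over all branch lengths.

        Uses outer partial likelihoods so each branch objective is cheap.
        Returns the log-likelihood after the sweep (fresh full pass).
        """
        cats = self.categories
        K = len(cats)
        S = self.space.n_states
        P = self.n_patterns
        self._downpass(keep=True)
        D, dlog = self._D, self._dlog
        lo, hi = np.log(bounds[0]), np.log(bounds[1])

        O: list = [None] * len(self._postorder)
        olog: list = [None] * len(self._postorder)
        ri = len(self._postorder) - 1
        O[ri] = np.stack([np.repeat(c.stationary[:, None], 1, axis=1) for c in cats])
        olog[ri] = np.zeros((K, P))

        w = self.weights
        for node in self.tree.preorder():
            if node.is_leaf and node.parent is None:
                break
            if node.is_leaf:
                continue
            ui = self._index[id(node)]
            Ou, ologu = O[ui], olog[ui]
            # transition-propagated child terms, updated as branches move
            Tc: dict[int, np.ndarray] = {}
            for child in node.children:
                ci = self._index[id(child)]
                Pc = self._pmats(child.length)
                Dc = D[ci]
                Tc[ci] = np.stack(
                    [Pc[k] @ (Dc if Dc.ndim == 2 else Dc[k]) for k in range(K)]
                )
            for child in node.children:
                ci = self._index[id(child)]
                G = np.broadcast_to(Ou, (K, S, P)).copy()
                glog = ologu.copy()
                for other in node.children:
                    oi = self._index[id(other)]
                    if oi == ci:
                        continue
                    G *= Tc[oi]
                    if isinstance(dlog[oi], np.ndarray):
                        glog += dlog[oi]
                m = G.max(axis=1)
                np.clip(m, _TINY, None, out=m)
                G /= m[:, None, :]
                glog += np.log(m)
                Dc = D[ci]
                base = glog + (dlog[ci] if isinstance(dlog[ci], np.ndarray) else 0.0)

                def neg_lnl(log_t: float) -> float:
                    t = float(np.exp(log_t))
                    logs = np.empty((K, P))
                    for k in range(K):
                        Pk = cats[k].spectral.expm(t)
                        X = Pk @ (Dc if Dc.ndim == 2 else Dc[k])
                        site = np.einsum("sp,sp->p", G[k], X)
                        logs[k] = np.log(np.clip(site, _TINY, None)) + base[k]
                    mx = logs.max(axis=0)
                    mixed = mx + np.log(np.exp(logs - mx).mean(axis=0))
                    return -float(w @ mixed)

                res = scipy.optimize.minimize_scalar(
                    neg_lnl, bounds=(lo, hi), method="bounded",
                    options={"xatol": xtol},
                )
                t_new = float(np.exp(res.x))
                if neg_lnl(np.log(max(child.length, bounds[0]))) >= res.fun:
                    child.length = t_new
                # refresh propagated term and outer partial with final length
                Pk_list = self._pmats(child.length)
                Tc[ci] = np.stack(
                    [Pk_list[k] @ (Dc if Dc.ndim == 2 else Dc[k]) for k in range(K)]
                )
                if not child.is_leaf:
                    Ov = np.stack([Pk_list[k].T @ G[k] for k in range(K)])
                    m = Ov.max(axis=1)
                    np.clip(m, _TINY, None, out=m)
                    Ov /= m[:, None, :]
                    O[ci] = Ov
                    olog[ci] = glog + np.log(m)
        self._D = self._dlog = None
        return self.log_likelihood()


def log_likelihood(
    tree: PhyloTree,
    aln: CountsAlignment,
    model: MutationModel,
    mix: GammaMixture | None = None,
    space: StateSpace | None = None,
    strategy: str = "wbinomial",
    seed: int = 0,
) -> float:
    """One-shot mixture log-likelihood of an alignment on a tree."""
    if space is None:
        space = StateSpace(10, aln.alphabet)
    engine = PruningEngine(tree, aln, space, strategy=strategy, seed=seed)
    engine.set_model(model, mix)
    return engine.log_likelihood()
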