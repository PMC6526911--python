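"""Maximum-likelihood estimation for the boundary mutation model.

Optimization is coordinate-wise: branch lengths are updated one at a time
in an outer-partial sweep (cheap 1-D objectives), then each free model
parameter (kappa or GTR exchangeabilities, heterozygosity theta, Gamma
shape alpha, optionally the base frequencies) is refined by a bounded 1-D
search on log scale.  Sweeps repeat until the log-likelihood gain drops
below tolerance.

The heterozygosity ``theta`` (stationary polymorphic mass) replaces the raw
mutation magnitude as the optimized parameter: whenever the exchangeability
parameters or frequencies move, the magnitude is recalibrated so ``theta``
keeps its meaning.  Base frequencies default to the empirical allele
frequencies of the alignment; maximum-likelihood frequencies are optional.

Also here: small-scale topology search (exhaustive or NNI hill-climbing),
nonparametric bootstrap support, and AIC/BIC model ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.optimize

from .alignment import CountsAlignment
from .gammamix import GammaMixture, discretize_gamma
from .likelihood import PruningEngine
from .mutation import MutationModel
from .phylotree import Node, PhyloTree
from .ratematrix import calibrate_heterozygosity, polymorphic_mass
from .statespace import StateSpace

__all__ = [
    "FitOptions",
    "FitResult",
    "Candidate",
    "fit",
    "search_topology",
    "bootstrap",
    "rank_models",
]


@dataclass
class FitOptions:
    """Knobs of the coordinate-wise optimizer.

    Bounds: branch lengths in [1e-8, 10] (log scale), kappa in [0.2, 100],
    alpha in [0.01, 1e6], theta in (1e-6, 0.25), exchangeabilities in
    [0.01, 100].
    """

    free_branch_lengths: bool = True
    free_rates: bool = True          # kappa (HKY) or exchangeabilities (GTR)
    free_theta: bool = True
    free_alpha: bool = True          # only meaningful with K > 1
    free_pi: bool = False            # ML frequencies instead of fixed/empirical
    max_sweeps: int = 100
    tol_lnl: float = 1e-4            # stop when a sweep gains less than this
    xtol: float = 1e-3               # 1-D tolerance on log-parameters
    branch_bounds: tuple[float, float] = (1e-8, 10.0)
    kappa_bounds: tuple[float, float] = (0.2, 100.0)
    alpha_bounds: tuple[float, float] = (0.01, 1e6)
    theta_bounds: tuple[float, float] = (1e-6, 0.25)
    rate_bounds: tuple[float, float] = (0.01, 100.0)
    local_window: float = 2.0        # bracket shrink factor after sweep 1


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    log_likelihood: float
    tree: PhyloTree
    model: MutationModel
    mix: GammaMixture
    estimates: dict
    n_free_parameters: int
    converged: bool
    n_sweeps: int

    def aic(self) -> float:
        return 2.0 * self.n_free_parameters - 2.0 * self.log_likelihood

    def bic(self, n_sites: float) -> float:
        return self.n_free_parameters * np.log(n_sites) - 2.0 * self.log_likelihood

    def report(self) -> str:
        lines = [f"lnL = {self.log_likelihood:.6f}"]
        for k, v in self.estimates.items():
            if isinstance(v, float):
                lines.append(f"{k} = {v:.6g}")
        lines.append(f"free parameters = {self.n_free_parameters}")
        lines.append(f"converged = {self.converged} ({self.n_sweeps} sweeps)")
        return "\n".join(lines)


class _ParamState:
    """Mutable (rates, pi, theta, alpha) state mapped onto engine models."""

    def __init__(self, engine: PruningEngine, model: MutationModel,
                 mix: GammaMixture, space: StateSpace):
        self.engine = engine
        self.space = space
        self.base = model
        self.theta = polymorphic_mass(space, model)
        self.alpha = mix.alpha if np.isfinite(mix.alpha) else np.inf
        self.K = mix.K
        self.kappa = model.kappa
        self.exch = model.gtr_rates if model.name == "GTR" else None
        self.pi = model.pi.copy()

    def model(self) -> MutationModel:
        if self.base.name == "HKY":
            m = MutationModel.hky(self.kappa, self.pi)
        elif self.base.name == "GTR":
            m = MutationModel.gtr(self.exch, self.pi)
        else:
            m = replace(self.base, pi=self.pi)
        return calibrate_heterozygosity(m, self.space, self.theta)

    def mix(self) -> GammaMixture:
        if self.K == 1:
            return discretize_gamma(self.alpha, 1) if np.isfinite(self.alpha) else GammaMixture.homogeneous()
        return discretize_gamma(self.alpha, self.K)

    def push(self) -> None:
        self.engine.set_model(self.model(), self.mix())

    def lnl(self) -> float:
        self.push()
        return self.engine.log_likelihood()


def _optimize_scalar(state: _ParamState, get, set_, bounds, xtol,
                     first_sweep: bool, window: float) -> float:
    """Bounded 1-D maximization over one log-scaled parameter."""
    x0 = get()
    lo, hi = bounds
    if not first_sweep:
        lo, hi = max(lo, x0 / window), min(hi, x0 * window)
    if hi <= lo:
        lo, hi = bounds

    def neg(logx: float) -> float:
        set_(float(np.exp(logx)))
        return -state.lnl()

    res = scipy.optimize.minimize_scalar(
        neg, bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": xtol},
    )
    best = float(np.exp(res.x))
    # keep the old value if the line search failed to improve on it
    set_(x0)
    f0 = -state.lnl()
    if res.fun <= f0:
        set_(best)
        return -res.fun
    return -f0


def fit(
    tree: PhyloTree,
    aln: CountsAlignment,
    model: MutationModel,
    mix: GammaMixture | None = None,
    space: StateSpace | None = None,
    strategy: str = "wbinomial",
    options: FitOptions | None = None,
    seed: int = 0,
) -> FitResult:
    """Maximize the mixture log-likelihood; returns a fitted copy of the tree."""
    if space is None:
        space = StateSpace(10, aln.alphabet)
    if mix is None:
        mix = GammaMixture.homogeneous()
    opts = options or FitOptions()
    work = tree.copy()
    engine = PruningEngine(work, aln, space, strategy=strategy, seed=seed)
    state = _ParamState(engine, model, mix, space)

    free_scalars = []
    if opts.free_rates and model.name == "HKY":
        free_scalars.append(
            ("kappa", lambda: state.kappa,
             lambda v: setattr(state, "kappa", v), opts.kappa_bounds)
        )
    if opts.free_rates and model.name == "GTR":
        for j in range(1, 6):  # AG exchangeability is the reference rate
            def get(j=j):
                return state.exch[j]

            def set_(v, j=j):
                state.exch[j] = v

            free_scalars.append((f"rho{j}", get, set_, opts.rate_bounds))
    if opts.free_theta:
        free_scalars.append(
            ("theta", lambda: state.theta,
             lambda v: setattr(state, "theta", v), opts.theta_bounds)
        )
    if opts.free_alpha and mix.K > 1 and np.isfinite(state.alpha):
        free_scalars.append(
            ("alpha", lambda: state.alpha,
             lambda v: setattr(state, "alpha", v), opts.alpha_bounds)
        )

    n_branches = sum(1 for n in work.postorder() if n.parent is not None)
    n_free = (n_branches if opts.free_branch_lengths else 0) + len(free_scalars)
    if opts.free_pi:
        n_free += space.alphabet.size - 1

    lnl = state.lnl()
    if n_free == 0:
        warnings.warn("no free parameters; returning likelihood evaluation only",
                      stacklevel=2)
        return _result(lnl, work, state, n_free, True, 0)

    converged = False
    sweeps = 0
    for sweep in range(opts.max_sweeps):
        sweeps = sweep + 1
        prev = lnl
        if opts.free_branch_lengths:
            state.push()
            lnl = engine.optimize_branches(bounds=opts.branch_bounds, xtol=opts.xtol)
        for _, get, set_, bounds in free_scalars:
            lnl = _optimize_scalar(
                state, get, set_, bounds, opts.xtol, sweep == 0, opts.local_window
            )
        if opts.free_pi:
            lnl = _optimize_pi(state)
        if lnl - prev < opts.tol_lnl:
            converged = True
            break
    return _result(lnl, work, state, n_free, converged, sweeps)


def _optimize_pi(state: _ParamState) -> float:
    """Nelder-Mead over softmax-parameterized base frequencies."""
    n = state.pi.size

    def unpack(z):
        e = np.exp(np.concatenate([[0.0], z]))
        return e / e.sum()

    z0 = np.log(state.pi[1:] / state.pi[0])

    def neg(z):
        state.pi = unpack(z)
        return -state.lnl()

    res = scipy.optimize.minimize(neg, z0, method="Nelder-Mead",
                                  options={"xatol": 1e-4, "fatol": 1e-6})
    state.pi = unpack(res.x)
    return -neg(res.x)


def _result(lnl, work, state, n_free, converged, sweeps) -> FitResult:
    model = state.model()
    mix = state.mix()
    estimates = {
        "theta": float(state.theta),
        "magnitude": float(model.magnitude),
        "branch_lengths": work.branch_lengths(),
        "pi": state.pi.copy(),
    }
    if state.kappa is not None:
        estimates["kappa"] = float(state.kappa)
    if state.exch is not None:
        estimates["gtr_rates"] = state.exch.copy()
    if np.isfinite(state.alpha) and state.K > 1:
        estimates["alpha"] = float(state.alpha)
    return FitResult(
        log_likelihood=float(lnl), tree=work, model=model, mix=mix,
        estimates=estimates, n_free_parameters=int(n_free),
        converged=bool(converged), n_sweeps=int(sweeps),
    )


# -- topology search ---------------------------------------------------------


def _enumerate_topologies(taxa: list[str]) -> list[PhyloTree]:
    """All unrooted binary topologies (trifurcating root representation)."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def trees(names):
        if len(names) == 3:
            root = Node()
            for nm in names:
                root.add_child(Node(nm, 0.01))
            yield PhyloTree(root)
            return
        last = names[-1]
        for sub in trees(names[:-1]):
            edges = [n for n in sub.postorder() if n.parent is not None]
            for k in range(len(edges)):
                t = sub.copy()
                edges_t = [n for n in t.postorder() if n.parent is not None]
                edge = edges_t[k]
                parent = edge.parent
                mid = Node(None, edge.length / 2.0)
                edge.length /= 2.0
                parent.children[parent.children.index(edge)] = mid
                mid.parent = parent
                mid.add_child(edge)
                mid.add_child(Node(last, 0.01))
                yield t

    return list(trees(list(taxa)))


def _nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """All trees one nearest-neighbour interchange away (unrooted semantics)."""
    out = []
    nodes = list(tree.postorder())
    for idx, v in enumerate(nodes):
        if v.is_leaf or v.parent is None:
            continue
        u = v.parent
        siblings = [c for c in u.children if c is not v]
        if u.parent is None:
            # trifurcating (unrooted) root: both flanking subtrees are partners;
            # a binary root is skipped -- callers unroot first
            if len(siblings) < 2:
                continue
            swap_partners = siblings
        else:
            if not siblings:
                continue
            swap_partners = siblings[:1]
        for s in swap_partners:
            for child in list(v.children):
                t = tree.copy()
                tn = list(t.postorder())
                v2 = tn[idx]
                u2 = v2.parent
                s2 = u2.children[u.children.index(s)]
                c2 = v2.children[v.children.index(child)]
                u2.children[u2.children.index(s2)] = c2
                v2.children[v2.children.index(c2)] = s2
                s2.parent, c2.parent = v2, u2
                out.append(t)
    return out


def search_topology(
    aln: CountsAlignment,
    model: MutationModel,
    mix: GammaMixture | None = None,
    space: StateSpace | None = None,
    strategy: str = "wbinomial",
    options: FitOptions | None = None,
    mode: str = "auto",
    start_tree: PhyloTree | None = None,
    seed: int = 0,
) -> FitResult:
    """Find the ML topology: exhaustively (<= 8 taxa) or by NNI hill-climbing."""
    n = len(aln.populations)
    if mode == "auto":
        mode = "exhaustive" if n <= 6 else "nni"
    if mode == "exhaustive":
        if n > 8:
            raise ValueError("exhaustive search supports at most 8 taxa; use mode='nni'")
        best = None
        for cand in _enumerate_topologies(list(aln.populations)):
            res = fit(cand, aln, model, mix, space, strategy, options, seed)
            if best is None or res.log_likelihood > best.log_likelihood:
                best = res
        return best
    if mode != "nni":
        raise ValueError(f"unknown search mode {mode!r}")
    if start_tree is None:
        rng = np.random.default_rng(seed)
        taxa = list(aln.populations)
        rng.shuffle(taxa)
        start_tree = _enumerate_topologies(taxa[:3])[0]
        for nm in taxa[3:]:
            edges = [x for x in start_tree.postorder() if x.parent is not None]
            edge = edges[rng.integers(len(edges))]
            parent = edge.parent
            mid = Node(None, edge.length / 2)
            edge.length /= 2
            parent.children[parent.children.index(edge)] = mid
            mid.parent = parent
            mid.add_child(edge)
            mid.add_child(Node(nm, 0.01))
    else:
        start_tree = start_tree.copy().unroot()
    best = fit(start_tree, aln, model, mix, space, strategy, options, seed)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbors(best.tree):
            res = fit(cand, aln, model, mix, space, strategy, options, seed)
            if res.log_likelihood > best.log_likelihood + 1e-6:
                best = res
                improved = True
                break
    return best


# -- bootstrap ---------------------------------------------------------------


def bootstrap(
    tree: PhyloTree,
    aln: CountsAlignment,
    model: MutationModel,
    mix: GammaMixture | None = None,
    B: int = 100,
    seed: int = 0,
    space: StateSpace | None = None,
    strategy: str = "wbinomial",
    options: FitOptions | None = None,
    search: str = "nni",
) -> pd.DataFrame:
    """Nonparametric bootstrap support for the splits of ``tree``.

    Site patterns are resampled with replacement (multinomial on pattern
    weights, identical in distribution to resampling columns); each
    replicate is refit -- with topology re-search unless ``search='none'``
    -- and each input split's support is the percentage of replicates whose
    tree contains it.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    ref_splits = tree.splits()
    hits = {s: 0 for s in ref_splits}
    for _ in range(B):
        idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
        rep = CountsAlignment(list(aln.populations), aln.counts[idx], aln.alphabet)
        if search == "none":
            res = fit(tree, rep, model, mix, space, strategy, options, seed)
        else:
            res = search_topology(
                rep, model, mix, space, strategy, options,
                mode="nni" if search == "nni" else search,
                start_tree=tree, seed=seed,
            )
        rep_splits = res.tree.splits()
        for s in ref_splits:
            if s in rep_splits:
                hits[s] += 1
    rows = [
        {"split": tuple(sorted(s)), "support": 100.0 * hits[s] / B}
        for s in sorted(ref_splits, key=lambda s: tuple(sorted(s)))
    ]
    return pd.DataFrame(rows, columns=["split", "support"])


# -- model ranking -----------------------------------------------------------


@dataclass
class Candidate:
    """One model-selection candidate: mutation model plus heterogeneity."""

    name: str
    model: MutationModel
    K: int = 1
    alpha: float = 1.0


def rank_models(
    aln: CountsAlignment,
    tree: PhyloTree,
    candidates: list[Candidate],
    criterion: str = "BIC",
    space: StateSpace | None = None,
    strategy: str = "wbinomial",
    options: FitOptions | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every candidate and rank by AIC or BIC (stable sort)."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidates to rank")
    if criterion.upper() not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    n_sites = float(aln.n_sites)
    rows = []
    fits = []
    for cand in candidates:
        mix = discretize_gamma(cand.alpha, cand.K) if cand.K > 1 else None
        try:
            res = fit(tree, aln, cand.model, mix, space, strategy, options, seed)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"candidate {cand.name!r} failed to fit: {exc}", stacklevel=2)
            continue
        rows.append(
            {
                "name": cand.name,
                "lnL": res.log_likelihood,
                "k": res.n_free_parameters,
                "AIC": res.aic(),
                "BIC": res.bic(n_sites),
            }
        )
        fits.append(res)
    table = pd.DataFrame(rows, columns=["name", "lnL", "k", "AIC", "BIC"])
    table = table.sort_values(criterion.upper(), kind="stable").reset_index(drop=True)
    return table
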