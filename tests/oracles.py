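"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written by a different route than the
library code: brute-force enumeration, scipy Pade matrix exponentials,
adaptive quadrature, and naive split dictionaries.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import scipy.integrate
import scipy.linalg
import scipy.stats


def exhaustive_log_likelihood(tree, aln, space, model, mix, strategy="wbinomial"):
    """Mixture log-likelihood by explicit summation over all internal-node
    state assignments, with scipy's Pade matrix exponential for every branch.

    Feasible only for tiny state spaces and 3-4 taxa.
    """
    from pomopy.gammamix import category_matrices
    from pomopy.leaflik import STRATEGIES, SiteObservation
    from pomopy.ratematrix import build_drift_matrix, build_mutation_matrix

    QM = build_mutation_matrix(space, model)
    QD = build_drift_matrix(space)
    cats = category_matrices(QM, QD, mix, space=space, model=model)
    S = space.n_states
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    root = nodes[-1]
    leaves = [n for n in nodes if n.is_leaf]
    pop_index = {pop: k for k, pop in enumerate(aln.populations)}

    init = STRATEGIES[strategy]
    # per-leaf likelihood matrices over (state, site)
    leaf_mat = {}
    for leaf in leaves:
        cols = []
        for site in range(aln.n_sites):
            row = aln.counts[site, pop_index[leaf.name]]
            obs = SiteObservation(row, missing=bool(row.sum() == 0))
            cols.append(init(obs, space))
        leaf_mat[id(leaf)] = np.stack(cols, axis=1)

    site_lik = np.zeros(aln.n_sites)
    for cat, weight in zip(cats, mix.weights):
        P = {
            id(n): scipy.linalg.expm(cat.Q * n.length)
            for n in nodes
            if n.parent is not None
        }
        # leaf contribution given the parent's state: (state, site)
        leaf_given_parent = {
            id(leaf): P[id(leaf)] @ leaf_mat[id(leaf)] for leaf in leaves
        }
        for assign in product(range(S), repeat=len(internal)):
            states = {id(n): s for n, s in zip(internal, assign)}
            scalar = cat.stationary[states[id(root)]]
            for n in internal:
                if n.parent is not None:
                    scalar *= P[id(n)][states[id(n.parent)], states[id(n)]]
            if scalar == 0.0:
                continue
            term = np.full(aln.n_sites, scalar)
            for leaf in leaves:
                term = term * leaf_given_parent[id(leaf)][states[id(leaf.parent)]]
            site_lik += weight * term
    return float(np.log(site_lik).sum())


def gamma_category_means_quadrature(alpha: float, K: int) -> np.ndarray:
    """Means of the K equal-probability slices of Gamma(alpha, mean 1) by
    adaptive quadrature."""
    dist = scipy.stats.gamma(a=alpha, scale=1.0 / alpha)
    edges = [0.0] + [dist.ppf(k / K) for k in range(1, K)] + [np.inf]
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = scipy.integrate.quad(lambda x: x * dist.pdf(x), lo, hi, limit=200)
        means.append(val * K)
    return np.asarray(means)


def closed_form_stationary(space, model) -> np.ndarray:
    """Reversible stationary measure assembled state by state from detailed
    balance (independent of the library's vectorized construction)."""
    S = space.n_states
    m = np.zeros(S)
    for idx, st in enumerate(space.states):
        ia = space.alphabet.index(st.first)
        if not st.is_polymorphic:
            m[idx] = model.pi[ia]
        else:
            ib = space.alphabet.index(st.second)
            rho = model.exchangeabilities[ia, ib]
            i = st.count
            m[idx] = (
                model.magnitude * rho * model.pi[ia] * model.pi[ib]
                * space.N / (i * (space.N - i))
            )
    return m / m.sum()


def tree_splits_with_lengths(tree) -> dict:
    """Naive unrooted split dictionary built by leaf-set recursion."""
    names = sorted(n.name for n in tree.leaves())
    ref, full = names[0], frozenset(names)

    out: dict[frozenset, float] = {}

    def walk(node) -> frozenset:
        if node.is_leaf:
            below = frozenset([node.name])
        else:
            below = frozenset().union(*(walk(c) for c in node.children))
        if node.parent is not None:
            side = full - below if ref in below else below
            out[side] = out.get(side, 0.0) + node.length
        return below

    walk(tree.root)
    return out


def branch_score_oracle(t1, t2) -> float:
    s1 = tree_splits_with_lengths(t1)
    s2 = tree_splits_with_lengths(t2)
    total = 0.0
    for split in set(s1) | set(s2):
        total += (s1.get(split, 0.0) - s2.get(split, 0.0)) ** 2
    return float(np.sqrt(total))


def robinson_foulds_oracle(t1, t2) -> int:
    n = len(t1.leaves())

    def nontrivial(splits):
        return {s for s in splits if 2 <= len(s) <= n - 2}

    s1 = nontrivial(tree_splits_with_lengths(t1))
    s2 = nontrivial(tree_splits_with_lengths(t2))
    return len(s1 ^ s2)


def bisect_magnitude_for_theta(space, model, theta, tol=1e-12) -> float:
    """Plain bisection on the numerically-computed stationary polymorphic
    mass as a function of the mutation magnitude."""
    from pomopy.ratematrix import (
        build_drift_matrix,
        build_mutation_matrix,
        stationary_numeric,
    )

    def mass(mu):
        QM = build_mutation_matrix(space, model.with_magnitude(mu))
        QD = build_drift_matrix(space)
        stat = stationary_numeric(QM + QD)
        return stat[space.polymorphic_mask].sum()

    lo, hi = 1e-12, 10.0
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if mass(mid) < theta:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
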