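import numpy as np
import pytest

import pomopy as pp

HKY_PI = np.array([0.3, 0.2, 0.2, 0.3])


@pytest.fixture(scope="session")
def space10():
    return pp.StateSpace(10)


@pytest.fixture(scope="session")
def space4():
    return pp.StateSpace(4)


@pytest.fixture(scope="session")
def hky():
    return pp.MutationModel.hky(6.25, HKY_PI.copy())


@pytest.fixture(scope="session")
def hky_calibrated(space10, hky):
    return pp.calibrate_heterozygosity(hky, space10, 0.0025)


def random_reversible_model(rng, alphabet=pp.DNA, magnitude=None):
    """Random GTR-style reversible model on the given alphabet."""
    n = alphabet.size
    pi = rng.dirichlet(np.full(n, 5.0))
    rho = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals = rng.uniform(0.2, 5.0, size=len(iu[0]))
    rho[iu] = vals
    rho += rho.T
    mu = magnitude if magnitude is not None else rng.uniform(1e-4, 1e-2)
    return pp.MutationModel.custom(rho, pi, mu, alphabet=alphabet)


def random_tree(rng, names, scale=0.3):
    """Random binary tree topology with exponential branch lengths."""
    nodes = [pp.Node(nm, float(rng.exponential(scale))) for nm in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = pp.Node(None, float(rng.exponential(scale)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    nodes[0].length = 0.0
    return pp.PhyloTree(nodes[0])
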