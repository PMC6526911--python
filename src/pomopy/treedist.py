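"""Tree comparison: branch score distance and Robinson-Foulds distance.

Both distances are computed under unrooted semantics (reversible models
make root placement arbitrary): rooted inputs are unrooted first.  The
branch score follows the Kuhner-Felsenstein convention, including pendant
branches; Robinson-Foulds counts non-trivial bipartitions present in
exactly one tree.  The split bookkeeping is delegated to dendropy.
"""

from __future__ import annotations

import dendropy

from .phylotree import PhyloTree

__all__ = ["normalize_height", "branch_score_distance", "robinson_foulds"]


def normalize_height(tree: PhyloTree) -> PhyloTree:
    """Return a copy rescaled so the maximum root-to-tip distance is 1.0."""
    h = tree.height()
    if h <= 0:
        raise ValueError("cannot normalize a tree of zero height")
    return tree.copy().scale(1.0 / h)


def _as_dendropy_pair(t1: PhyloTree, t2: PhyloTree):
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees have different leaf sets")
    ns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=t1.newick(), schema="newick", taxon_namespace=ns)
    d2 = dendropy.Tree.get(data=t2.newick(), schema="newick", taxon_namespace=ns)
    for d in (d1, d2):
        d.is_rooted = False
        d.collapse_basal_bifurcation()
        d.encode_bipartitions()
    return d1, d2


def branch_score_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """Kuhner-Felsenstein branch score: sqrt of summed squared length
    differences over the union of bipartitions (0 for absent splits)."""
    d1, d2 = _as_dendropy_pair(t1, t2)
    return float(dendropy.calculate.treecompare.euclidean_distance(d1, d2))


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of non-trivial bipartitions present in exactly one tree."""
    d1, d2 = _as_dendropy_pair(t1, t2)
    return int(dendropy.calculate.treecompare.symmetric_difference(d1, d2))
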