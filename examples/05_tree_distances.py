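"""Comparing species trees: branch score and Robinson-Foulds distances.

Both distances treat trees as unrooted.  Height normalization (rescaling so
the root-to-tip distance is 1) makes branch scores comparable across
analyses with different time scales; it never changes the Robinson-Foulds
distance, which only counts topological differences.
"""

import pomopy as pp

t1 = pp.PhyloTree.from_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
t2 = pp.PhyloTree.from_newick("((A:2,B:2):1.0,(C:2,D:2):1.0);")
t3 = pp.PhyloTree.from_newick("((A:1,C:1):0.5,(B:1,D:1):0.5);")

print("same topology, doubled lengths:")
print("  bsd =", pp.branch_score_distance(t1, t2), " rf =", pp.robinson_foulds(t1, t2))
n1, n2 = pp.normalize_height(t1), pp.normalize_height(t2)
print("after height normalization:")
print("  bsd =", pp.branch_score_distance(n1, n2), " rf =", pp.robinson_foulds(n1, n2))
print("different topology:")
print("  bsd =", round(pp.branch_score_distance(t1, t3), 4),
      " rf =", pp.robinson_foulds(t1, t3))
print("rf counts bipartitions found in exactly one tree (2 here: AB and CD "
      "versus AC and BD); bsd additionally weighs branch-length differences.")
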