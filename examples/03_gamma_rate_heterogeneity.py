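"""Mutation-rate heterogeneity as a mixture of generators.

Only the mutation part of the generator is scaled by the per-category rate
modifiers (the means of K equal-probability slices of a mean-one Gamma);
drift is shared.  The mixture log-likelihood with a huge shape parameter
collapses onto the homogeneous model.
"""

import numpy as np

import pomopy as pp

mix = pp.discretize_gamma(alpha=0.5, K=4)
print("category rate modifiers (alpha=0.5):", np.round(mix.rates, 4))
print("their mean is exactly 1:", mix.weights @ mix.rates)

space = pp.StateSpace(10)
model = pp.calibrate_heterozygosity(
    pp.MutationModel.hky(6.25, [0.3, 0.2, 0.2, 0.3]), space, 0.0025
)

tree = pp.sample_yule_tree(pp.YuleSpec(6, 1.0), seed=3)
cfg = pp.SimConfig(n_sites=5000, tree=tree, theta=0.0025, alpha=0.5, K=4, seed=9)
aln, true_tree, _ = pp.simulate_alignment(cfg)

lnl_het = pp.log_likelihood(true_tree, aln, model, mix, space)
lnl_hom = pp.log_likelihood(true_tree, aln, model, None, space)
lnl_degenerate = pp.log_likelihood(true_tree, aln, model, pp.discretize_gamma(1e6, 4), space)
print(f"lnL with matching heterogeneity: {lnl_het:.2f}")
print(f"lnL homogeneous:                 {lnl_hom:.2f}")
print(f"lnL degenerate mixture (alpha=1e6): {lnl_degenerate:.2f} "
      "(equals the homogeneous value)")
print("the heterogeneous model fits data simulated with rate variation better.")
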