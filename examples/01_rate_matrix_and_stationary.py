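"""Build the boundary-mutation-model generator and inspect its stationary law.

The PoMo state space for N=10 virtual individuals over A,C,G,T has
58 states: 4 monomorphic plus 6 allele pairs x 9 frequency bins.  The
generator is Q = QM + QD (mutation from monomorphic states only, Moran
drift between neighbouring bins), and the mutation magnitude is calibrated
so that the stationary probability of being polymorphic equals a target
heterozygosity.
"""

import numpy as np

import pomopy as pp

space = pp.build_state_space(10)
print(f"state space: N={space.N}, {len(space)} states")

model = pp.MutationModel.hky(kappa=6.25, pi=[0.3, 0.2, 0.2, 0.3])
model = pp.calibrate_heterozygosity(model, space, theta=0.005)
print(f"calibrated mutation magnitude mu = {model.magnitude:.6g} "
      "(sets stationary polymorphic mass to 0.005)")

QM = pp.build_mutation_matrix(space, model)
QD = pp.build_drift_matrix(space)
rates = pp.assemble_rate_matrix(QM, QD)
print(f"normalization: {rates.scale:.6g} events/site per unit branch length")

stat = rates.stationary
poly = stat[space.polymorphic_mask].sum()
print(f"stationary polymorphic mass: {poly:.6f} (the calibrated heterozygosity)")
print(f"monomorphic masses A,C,G,T: {np.round(stat[:4] / stat[:4].sum(), 4)} "
      "(proportional to pi)")

factor = pp.events_per_substitution(space, model)
print(f"events per substitution: {factor:.1f} (= N^2; converts branch-length units)")
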