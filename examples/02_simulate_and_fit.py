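"""Simulate a two-trait triplet study and recover its parameters by EM.

Generates 800 test takers answering 6 triplets under the medium-slope
mixed-direction condition, fits the pattern model by quadrature EM, and
compares estimates with the generating truth.
"""

import numpy as np

import mgppm as mg
from mgppm.em import EMConfig, fit_em_quadrature

R = np.array([[1.0, 0.4], [0.4, 1.0]])
blocks = mg.build_design(n_traits=2, statements_per_trait=9, block_size=3)
blocks = mg.apply_keyed_directions(blocks, "mixed")
cond = mg.SimulationCondition("medium", "mixed", "triplet", n_persons=800, seed=1)
rng = np.random.default_rng(1)
params = mg.draw_item_parameters(blocks, cond, rng, R=R)
thetas = mg.draw_thetas(800, R, rng)
responses = mg.simulate_responses(blocks, params, thetas, rng)

result = fit_em_quadrature(responses, blocks, EMConfig(seed=1))

true_vec = params.item_vector(blocks)
est_vec = result.params.item_vector(blocks)
print(f"converged: {result.converged} after {result.n_cycles} EM cycles")
print(f"marginal log-likelihood: {result.loglik:.1f}  AIC: {result.aic:.1f}")
print(f"item-parameter correlation with truth: "
      f"{np.corrcoef(true_vec, est_vec)[0, 1]:.3f}")
print(f"intertrait correlation: true 0.40, estimated {result.params.R[0, 1]:.3f} "
      f"(SE {result.se_correlations[0]:.3f})")
print("a correlation near 1 and an estimate within ~2 SEs of 0.40 show the")
print("marginal-likelihood machinery recovers the generating parameters")
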