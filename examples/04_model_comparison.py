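"""Compare the pattern model against the sequential-selection baseline.

Simulates pattern-model triplet data (two traits so the quick quadrature
backend applies), fits both models with the same marginal-maximum-
likelihood machinery, and compares fit and trait-score agreement.
"""

import numpy as np

import mgppm as mg
from mgppm.diagnostics import compare_models
from mgppm.em import EMConfig

R = np.array([[1.0, 0.4], [0.4, 1.0]])
blocks = mg.build_design(n_traits=2, statements_per_trait=9, block_size=3)
blocks = mg.apply_keyed_directions(blocks, "mixed")
cond = mg.SimulationCondition("medium", "mixed", "triplet", n_persons=800, seed=5)
rng = np.random.default_rng(5)
params = mg.draw_item_parameters(blocks, cond, rng, R=R)
thetas = mg.draw_thetas(800, R, rng)
responses = mg.simulate_responses(blocks, params, thetas, rng)

report = compare_models(responses, blocks, EMConfig(seed=5))

print(f"pattern model:    loglik {report.fit_mgppm.loglik:9.1f}  "
      f"AIC {report.fit_mgppm.aic:9.1f}")
print(f"sequential model: loglik {report.fit_sequential.loglik:9.1f}  "
      f"AIC {report.fit_sequential.aic:9.1f}")
print(f"AIC difference (sequential - pattern): {report.aic_difference:.1f}")
print(f"BIC difference: {report.bic_difference:.1f} "
      "(equal because both models have the same free-parameter count)")
print(f"per-trait MAP score correlation between models: "
      + " ".join(f"{c:.3f}" for c in report.score_correlations))
print("\na positive AIC difference favours the generating pattern model,")
print("yet the two models' trait scores remain nearly interchangeable")
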