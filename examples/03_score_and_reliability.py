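"""MAP trait scores and empirical reliability at study scale.

Simulates the full 5-trait, 20-triplet design (medium slopes, mixed keyed
directions), scores every person by MAP with the true item parameters, and
compares the empirical reliability of each trait's scores with the squared
correlation between estimated and true traits.
"""

import numpy as np

import mgppm as mg
from mgppm.scoring import empirical_reliability, map_score

cond = mg.SimulationCondition("medium", "mixed", "triplet", n_persons=1000, seed=3)
study = mg.simulate_condition(cond)

scores = map_score(study.responses, study.blocks, study.params)
est_rel = empirical_reliability(scores)

print(f"{'trait':>6} {'cor(MAP, true)':>15} {'true rel':>10} {'est rel':>9}")
for d in range(5):
    r = np.corrcoef(scores.theta[:, d], study.thetas[:, d])[0, 1]
    print(f"{d + 1:>6} {r:>15.3f} {r ** 2:>10.3f} {est_rel[d]:>9.3f}")
print("\n'true rel' is the squared correlation with the generating traits;")
print("the empirical reliability V/(V + mean SE^2) should track it closely")
print(f"MAP scores shrink toward the prior: var(theta_hat) = "
      f"{scores.theta.var(axis=0).mean():.2f} < 1")
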