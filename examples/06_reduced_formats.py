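"""Reduced response formats: PICK, MOLE, graded pairs, and HFCL.

Shows how partial responses marginalize over their compatible full
rankings, and how graded and hybrid forced-choice/Likert blocks reuse the
same pattern machinery with different scoring functions.
"""

import numpy as np

import mgppm as mg
from mgppm.blocks import Block, Statement, hfcl_pattern_space
from mgppm.model import marginal_response_probability, pattern_probabilities

stmts = [Statement(k + 1, trait=k, slope=s, intercept=c)
         for k, (s, c) in enumerate([(0.9, 0.0), (1.3, 0.2), (-1.1, -0.3),
                                     (0.7, 0.1)])]
tetrad = Block(1, stmts)
theta = np.array([0.8, -0.2, 0.5, -0.6])

p_pick = marginal_response_probability(tetrad, ("pick", 2), theta)
p_mole = marginal_response_probability(tetrad, ("mole", 2, 3), theta)
probs = pattern_probabilities(tetrad, theta)
manual_pick = sum(p for pat, p in zip(tetrad.patterns, probs) if pat[0] == 2)

print(f"P(pick statement 2)          = {p_pick:.4f} "
      f"(sum over 6 compatible rankings: {manual_pick:.4f})")
print(f"P(most = 2, least = 3)       = {p_mole:.4f} "
      "(sum over the 2 rankings with 2 first and 3 last)")
pick_total = sum(marginal_response_probability(tetrad, ("pick", s), theta)
                 for s in range(1, 5))
print(f"PICK probabilities sum to    = {pick_total:.4f}")

graded = Block(2, stmts[:2], fmt="GRADED", n_categories=5)
print(f"\ngraded pair, 5 categories: P = "
      + " ".join(f"{p:.3f}" for p in pattern_probabilities(graded, theta)))
print("category g scores the pair (5-g, g-1): the scale end points fully")
print("favour one statement, middle categories split the credit")

hfcl = Block(3, stmts[:2], fmt="HFCL", n_categories=4)
space = hfcl_pattern_space(2, 4)
p_hfcl = pattern_probabilities(hfcl, theta)
best = np.argmax(p_hfcl)
print(f"\nHFCL pair, 4 categories, {len(space)} legal no-tie rating vectors;")
print(f"most likely rating vector at this theta: {space[best]} "
      f"(P = {p_hfcl[best]:.3f}); statement scores are 'rating - 1'")
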