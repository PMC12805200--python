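"""Ranking-pattern probabilities of a forced-choice triplet.

Builds one triplet whose three statements measure different traits, then
shows how the pattern model turns statement utilities into probabilities
over all six rankings, and how the log odds of two rankings decompose into
partial-credit utility differences.
"""

import numpy as np

from mgppm import (
    conditional_logit,
    enumerate_patterns,
    pattern_probabilities,
)
from mgppm.blocks import Block, Statement

block = Block(1, [
    Statement(1, trait=0, slope=0.64, intercept=0.0),
    Statement(2, trait=1, slope=1.28, intercept=0.30),
    Statement(3, trait=2, slope=2.00, intercept=-0.20),
])

theta = np.array([1.0, 0.0, -1.0])   # high on trait 1, low on trait 3
probs = pattern_probabilities(block, theta)

print("person traits:", theta)
print(f"{'ranking':>10} {'probability':>12}")
for pattern, p in zip(enumerate_patterns(3), probs):
    print(f"{str(pattern):>10} {p:>12.4f}")
print(f"{'sum':>10} {probs.sum():>12.4f}")

# the log odds of swapping ranks 1 and 2 equals the difference of the
# two statements' utilities: one rank level = one utility increment
logit = conditional_logit(block, theta, 1, 3)   # (1,2,3) vs (2,1,3)
u1 = 0.64 * theta[0] + 0.0
u2 = 1.28 * theta[1] + 0.30
print(f"\nlog P(1,2,3)/P(2,1,3) = {logit:.4f}  (= u1 - u2 = {u1 - u2:.4f})")
print("the most likely ranking puts the highest-utility statement first;")
print("probabilities sum to one over all 3! = 6 rankings")
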