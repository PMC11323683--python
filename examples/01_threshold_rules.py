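"""Threshold rules and their induced penalties.

The soft rule shifts values toward zero by λ and kills anything inside
[−λ, λ]; the hard rule keeps values outside the dead zone untouched.  Each
rule's penalty is recovered from the inverse-integral construction: soft
induces the lasso penalty λ|θ|, hard a capped quadratic.
"""

import numpy as np

from spatialipod import apply_threshold, induced_penalty, theta_hard, theta_soft

x = np.array([-3.0, -1.2, -0.4, 0.0, 0.8, 1.5, 4.0])
lam = 1.0

print("x          :", x)
print("soft(x; 1) :", theta_soft(x, lam))
print("hard(x; 1) :", theta_hard(x, lam))

# per-coordinate thresholds, as used inside the solver (λ_i = λ√(1−h_i))
lams = np.array([0.5, 0.5, 0.5, 1.0, 1.0, 2.0, 2.0])
print("per-coord soft:", apply_threshold(x, lams, "soft"))

for rule in ("soft", "hard"):
    pen = [induced_penalty(t, lam, rule) for t in (0.5, 1.0, 2.0)]
    print(f"penalty P_{rule}(θ; λ=1) at θ=0.5,1,2 :", np.round(pen, 4))

# The hard penalty plateaus at λ²/2 = 0.5: once a shift exceeds the
# threshold its size is no longer penalized, which is what leaves flagged
# outliers unshrunk.
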