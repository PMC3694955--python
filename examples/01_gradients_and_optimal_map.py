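"""Exponential Eph/ephrin gradients and the closed-form optimal map.

Builds a matched gradient set (identity map) and a mismatched one, and
compares the closed-form optimal SC position with a brute-force grid
argmin of the molecular branching inhibition.
"""

import numpy as np

import retinotopy as rt

matched = rt.matched_gradient_set(height=1.0, rate=2.0)
print("matched gradients: y(x) = x")
for x in (0.1, 0.5, 0.9):
    print(f"  x={x:.1f} -> closed form {rt.optimal_position_closed_form(x, matched):.4f}"
          f", brute force {rt.optimal_position_bruteforce(x, matched):.4f}")

# doubling the retinal EphA height shifts every optimum rostrally
doubled = rt.build_gradient_set(2, 1, 1, 1, 1, 1, 1, 1)
shift = rt.optimal_position_closed_form(0.5, doubled) - 0.5
print(f"\nretinal EphA height doubled: uniform shift {shift:+.4f}"
      f" (= -ln2/2 = {-np.log(2)/2:+.4f})")
print("a rostral (negative) shift: more axonal EphA means more forward"
      " repulsion from the caudal ephrin-A gradient")
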