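"""Winding numbers on constructed trajectories.

Shows that the winding number counts rotations in turns: a near-closed
circle winds once, a double-frequency orbit winds twice, time reversal flips
the sign, and a noise trajectory drifts with no systematic rotation.
"""

import numpy as np

from cyclefe import partial_winding, winding_number

m = 25
ang = 2 * np.pi * np.arange(m) / m
circle = np.column_stack([np.cos(ang), np.sin(ang)])

w, steps = winding_number(circle, center=False)
print(f"one loop, {m} points: W = {w:.3f} turns  (≈ (m-1)/m of a full turn)")

w_rev, _ = winding_number(circle[::-1], center=False)
print(f"time-reversed loop:      W = {w_rev:.3f}  (orientation flips the sign)")

double = np.column_stack([np.cos(2 * ang), np.sin(2 * ang)])
w2, _ = winding_number(double, center=False)
print(f"double frequency orbit:  W = {w2:.3f}  (winds once per half period)")

rng = np.random.default_rng(1)
w_noise, steps_noise = winding_number(rng.uniform(-1, 1, size=(m, 2)))
print(f"uniform noise:           W = {w_noise:+.3f}  (random walk around 0)")

run = partial_winding(steps)
print("running W over the loop:", np.round(run[:: m // 5], 2))
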