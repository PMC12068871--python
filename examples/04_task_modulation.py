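"""Six task-modulation tests and the movement-window Fano factor.

Builds a 150-trial behavioral session and a unit that doubles its firing
rate for 200 ms after movement onset, then runs the six window
comparisons (signed-rank for paired pre/post windows, rank-sum for
left-vs-right splits) and the Fano factor of movement-window counts.
"""

import numpy as np

from reprophys import (
    fano_factor,
    gen_event_locked_train,
    gen_trial_table,
    modulation_tests,
)

trials = gen_trial_table(400, seed=0)
duration = float(trials["feedback_time"].iloc[-1] + 2)
moves = trials["first_move"].to_numpy()

spikes = gen_event_locked_train(
    10.0, moves, lambda t: 10.0 * ((t >= 0) & (t < 0.2)), duration, seed=0
)
results = modulation_tests(spikes, trials)

print("test                        p-value  modulated  magnitude (sp/s)")
for name, r in results.items():
    mod = {True: "yes", False: "no", None: "undetermined"}[r.modulated]
    print(f"{name:27s} {r.p_value:7.4f}  {mod:9s}  {r.magnitude:+.2f}")

ff = fano_factor(spikes, trials)
print(f"\nFano factor (40-200 ms post-movement, full-contrast right trials): {ff:.2f}")
print(
    "\nThe movement-aligned tests detect the injected doubling; the"
    "\nstimulus-side split stays at chance because the response ignores"
    "\nthe stimulus. A Fano factor of 1 marks Poisson-like count"
    "\nvariability; refractoriness pushes it slightly below 1."
)
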