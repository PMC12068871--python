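"""Probe-targeting variability: trajectory fits, surface displacement and
angle deviation, fed into the cross-lab permutation test.
"""

import numpy as np

from reprophys import (
    PLANNED_REPEATED_SITE,
    REGIONS,
    SynthConfig,
    angle_difference,
    fit_trajectory,
    gen_multilab_population,
    permutation_test,
    surface_displacement,
)

# Fit a line to noisy traced track points.
rng = np.random.default_rng(0)
true_dir = PLANNED_REPEATED_SITE.direction
points = (
    PLANNED_REPEATED_SITE.entry
    + np.outer(np.linspace(0, 4000, 40), true_dir)
    + rng.normal(0, 20.0, (40, 3))
)
traj = fit_trajectory(points)
ang = np.degrees(np.arccos(abs(traj.direction @ true_dir)))
print(f"fitted direction deviates {ang:.3f} deg from truth (20 um tracing noise)")

# Displacement and angle statistics over a synthetic population.
cfg = SynthConfig(
    seed=3, n_labs=10, mice_per_lab=4,
    units_per_region={r: 0 for r in REGIONS}, n_trials=1, n_channels=4,
)
population = gen_multilab_population(cfg)
disps, angles, labels = [], [], []
for s in population:
    d_ap, d_ml, dist = surface_displacement(s.histology_traj, s.planned_traj)
    disps.append(dist)
    angles.append(angle_difference(s.histology_traj, s.planned_traj)[0])
    labels.append(s.lab_id)
print(f"mean surface displacement: {np.mean(disps):.0f} um")
print(f"mean angle deviation:      {np.mean(angles):.1f} deg")

res = permutation_test(np.array(disps), np.array(labels), n_perm=10000, seed=0)
print(f"lab effect on displacement: max-CDF = {res.statistic:.3f}, p = {res.p_value:.2f}")
print(
    "\nTargeting error is sizeable per insertion but carries no lab"
    "\nsignature here: the permutation test stays non-significant at the"
    "\nstringent alpha = 0.01, as expected for mouse-level noise."
)
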