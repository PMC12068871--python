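"""Classifier-with-shuffle-null test: can lab identity be decoded from
per-recording electrophysiological markers?

Computes five features per synthetic recording (yield, mean firing rate,
LFP band power, AP-band RMS, spike amplitude), trains a random forest to
predict the lab, and compares its cross-validated accuracy with a null
built by shuffling the lab labels.
"""

import numpy as np

from reprophys import REGIONS, SynthConfig, decode_group_null, gen_multilab_population

cfg = SynthConfig(
    seed=8, n_labs=5, mice_per_lab=4,
    units_per_region={r: 3 for r in REGIONS}, n_trials=60, n_channels=32,
)
population = gen_multilab_population(cfg)

rows, labels = [], []
for s in population:
    band = (s.lfp_freqs >= 20) & (s.lfp_freqs <= 80)
    rows.append(
        [
            len(s.units) / len(s.channel_depths),
            float(np.mean([u.n_spikes / s.duration for u in s.units])),
            float(np.mean(s.lfp_psd[:, band])),
            float(np.median(s.ap_rms_per_channel)),
            float(np.mean([np.median(u.amplitudes) for u in s.units])),
        ]
    )
    labels.append(s.lab_id)

res = decode_group_null(
    np.array(rows), np.array(labels), n_shuffles=200, seed=0, n_estimators=100
)
chance = 1.0 / len(res.classes)
print(f"recordings: {len(rows)}, labs: {len(res.classes)} (chance = {chance:.2f})")
print(f"cross-validated accuracy: {res.accuracy:.2f}")
print(f"shuffle-null p-value:     {res.p_value:.3f}")
print(
    "\nAccuracy near chance with a non-significant p-value means no"
    "\ncombination of the five markers betrays where a recording was"
    "\nmade — the multivariate reproducibility check."
)
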