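"""The ordered session-exclusion cascade.

Recreates the bookkeeping of a 121-session multi-lab campaign: sessions
fail acquisition, visual-QC, computed-QC or behavioral criteria in a
fixed order, each counted against the first criterion it fails, and labs
must retain at least three sessions to enter across-lab comparisons.
"""

import numpy as np
import pandas as pd

from reprophys import SessionRecord, exclusion_cascade


def bare_session(lab, sid, ledger=None, n_trials=450):
    t = np.arange(n_trials, dtype=float) * 3.0 + 1.0
    trials = pd.DataFrame(
        {
            "stim_on": t, "contrast": 1.0, "side": "left", "block_p_left": 0.5,
            "first_move": t + 0.2, "choice": "left", "feedback_type": "reward",
            "feedback_time": t + 0.3, "reaction_time": 0.2,
        }
    )
    return SessionRecord(
        lab_id=lab, subject_id=lab, session_id=sid, units=[],
        n_channels_per_region={}, channel_depths=np.array([0.0, 10.0]),
        ap_rms_per_channel=np.array([10.0, 10.0]), lfp_psd=np.zeros((2, 3)),
        lfp_freqs=np.array([20.0, 50.0, 80.0]), trial_table=trials,
        duration=100.0, exclusion_ledger=dict(ledger or {}),
    )


failures = [
    ("hardware", 10), ("histology", 8), ("drift", 1), ("noisy_channels", 10),
    ("artefacts", 2), ("epileptiform", 1), ("low_yield", 1), ("noise_level", 1),
]
sessions, i = [], 0
for crit, count in failures:
    for _ in range(count):
        sessions.append(bare_session(f"lab_{i % 10}", f"s{i}", {crit: False}))
        i += 1
for _ in range(5):  # too few completed trials
    sessions.append(bare_session(f"lab_{i % 10}", f"s{i}", n_trials=350))
    i += 1
while i < 121:
    sessions.append(bare_session(f"lab_{i % 10}", f"s{i}"))
    i += 1

survivors, tally = exclusion_cascade(sessions)
print(f"recorded sessions: {len(sessions)}")
for crit, n in tally.items():
    if n:
        print(f"  excluded by {crit}: {n}")
print(f"surviving sessions: {len(survivors)}")
print(
    "\nEach session counts against the first criterion it fails, so the"
    "\nper-criterion tallies and the survivor count partition the input."
)
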