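import numpy as np
import pytest

from reprophys import REGIONS, SessionRecord, SynthConfig, gen_multilab_population


def make_bare_session(
    lab="lab_00",
    subject="m00",
    session_id="s00",
    ledger=None,
    n_trials=None,
):
    """Minimal session carrying only what the exclusion cascade inspects."""
    import pandas as pd

    trials = None
    if n_trials is not None:
        t = np.arange(n_trials, dtype=float) * 3.0 + 1.0
        trials = pd.DataFrame(
            {
                "stim_on": t,
                "contrast": 1.0,
                "side": "left",
                "block_p_left": 0.5,
                "first_move": t + 0.2,
                "choice": "left",
                "feedback_type": "reward",
                "feedback_time": t + 0.3,
                "reaction_time": 0.2,
            }
        )
    return SessionRecord(
        lab_id=lab,
        subject_id=subject,
        session_id=session_id,
        units=[],
        n_channels_per_region={},
        channel_depths=np.array([0.0, 10.0]),
        ap_rms_per_channel=np.array([10.0, 10.0]),
        lfp_psd=np.zeros((2, 3)),
        lfp_freqs=np.array([20.0, 50.0, 80.0]),
        trial_table=trials,
        duration=100.0,
        exclusion_ledger=dict(ledger or {}),
    )


@pytest.fixture(scope="session")
def small_population():
    """A compact multi-lab population reused by several suites."""
    cfg = SynthConfig(
        seed=1234,
        n_labs=4,
        mice_per_lab=1,
        units_per_region={r: 3 for r in REGIONS},
        n_trials=100,
        n_channels=64,
    )
    return gen_multilab_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
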