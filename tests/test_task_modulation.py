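"""Task-modulation tests: window arithmetic, signed-rank/rank-sum
behaviour, null calibration, injected-effect power, and the Fano factor."""

import numpy as np
import pytest

from reprophys import (
    DEFAULT_WINDOWS,
    fano_factor,
    gen_event_locked_train,
    gen_spike_train,
    gen_trial_table,
    modulation_tests,
    proportion_modulated,
    trial_window_rates,
)


class TestTrialWindowRates:
    def test_no_spikes(self):
        rates = trial_window_rates(np.empty(0), np.array([1.0, 2.0]), (0.0, 0.2))
        np.testing.assert_array_equal(rates, 0.0)

    def test_half_open_convention(self):
        spikes = np.array([1.0, 1.2])
        # Spike exactly at event + w0 counts; at event + w1 it does not.
        assert trial_window_rates(spikes, np.array([1.0]), (0.0, 0.2))[0] == 5.0
        # A spike landing exactly at event + w1 is excluded.
        assert trial_window_rates(spikes, np.array([0.8]), (0.0, 0.2))[0] == 0.0

    def test_uniform_train_recovers_rate(self):
        spikes = np.arange(0, 100, 0.1)  # 10 spikes/s exactly
        rates = trial_window_rates(spikes, np.arange(5.0, 90.0, 7.0), (-0.5, 0.5))
        np.testing.assert_allclose(rates, 10.0)

    def test_missing_events_yield_nan(self):
        rates = trial_window_rates(
            np.arange(10.0), np.array([1.0, np.nan, 3.0]), (0.0, 1.0)
        )
        assert np.isnan(rates[1]) and np.isfinite(rates[[0, 2]]).all()

    def test_zero_width_window(self):
        with pytest.raises(ValueError):
            trial_window_rates(np.empty(0), np.array([1.0]), (0.2, 0.2))


class TestModulationTests:
    def test_identical_pre_post_not_modulated(self):
        trials = gen_trial_table(80, seed=0)
        # A metronome-like train has identical counts in equal-width
        # windows, so all paired differences are zero.
        dur = trials.feedback_time.iloc[-1] + 2
        spikes = np.arange(0, dur, 0.01)
        res = modulation_tests(spikes, trials)
        for name in ("movement_initiation", "feedback"):
            assert res[name].p_value == 1.0 and res[name].modulated is False

    def test_silent_unit_undetermined(self):
        trials = gen_trial_table(80, seed=1)
        res = modulation_tests(np.empty(0), trials)
        # Paired zero rates give p = 1; split tests on all-zero rates are
        # determined but not modulated. No spurious modulation either way.
        assert all(v.modulated in (False, None) for v in res.values())

    def test_too_few_trials_undetermined(self):
        trials = gen_trial_table(4, seed=2)
        res = modulation_tests(np.arange(0, 50, 0.05), trials)
        assert all(v.modulated is None for v in res.values())

    def test_movement_doubling_detected(self):
        # A unit doubling its rate after movement onset is detected by the
        # movement-initiation test with near-certain power at 100 trials.
        detected = 0
        n_seeds = 25
        for seed in range(n_seeds):
            trials = gen_trial_table(100, seed=seed)
            dur = trials.feedback_time.iloc[-1] + 2
            moves = trials.first_move.to_numpy()
            spikes = gen_event_locked_train(
                10.0, moves, lambda t: 10.0 * ((t >= 0) & (t < 0.2)), dur, seed=seed
            )
            res = modulation_tests(spikes, trials)
            detected += bool(res["movement_initiation"].modulated)
            assert res["movement_initiation"].magnitude > 0 or not res[
                "movement_initiation"
            ].modulated
        assert detected / n_seeds > 0.95

    def test_null_rejection_rate_calibrated(self):
        # Stationary Poisson units: each test should reject at roughly the
        # nominal 5% level (discrete counts make the signed-rank slightly
        # conservative or liberal within a few percent).
        trials = gen_trial_table(150, seed=99)
        dur = trials.feedback_time.iloc[-1] + 2
        rej = {k: 0 for k in DEFAULT_WINDOWS}
        det = {k: 0 for k in DEFAULT_WINDOWS}
        for i in range(300):
            spikes = gen_spike_train(15.0, dur, seed=5000 + i)
            for k, v in modulation_tests(spikes, trials).items():
                if v.modulated is not None:
                    det[k] += 1
                    rej[k] += v.modulated
        for k in DEFAULT_WINDOWS:
            rate = rej[k] / det[k]
            assert 0.01 < rate < 0.09, (k, rate)


class TestFanoFactor:
    def _trials_with_counts(self, counts):
        import pandas as pd

        n = len(counts)
        t = np.arange(n) * 10.0 + 5.0
        trials = pd.DataFrame(
            {
                "stim_on": t,
                "contrast": 1.0,
                "side": "right",
                "block_p_left": 0.5,
                "first_move": t + 0.2,
                "choice": "right",
                "feedback_type": "reward",
                "feedback_time": t + 0.5,
                "reaction_time": 0.2,
            }
        )
        spikes = np.concatenate(
            [
                trials.first_move[i] + 0.05 + np.arange(c) * 0.001
                for i, c in enumerate(counts)
            ]
        )
        return np.sort(spikes), trials

    def test_hand_example(self):
        spikes, trials = self._trials_with_counts([1, 3])
        # counts {1, 3}: mean 2, unbiased variance 2, FF = 1 exactly.
        assert fano_factor(spikes, trials) == pytest.approx(1.0)

    def test_identical_counts_zero(self):
        spikes, trials = self._trials_with_counts([4] * 10)
        assert fano_factor(spikes, trials) == 0.0

    def test_poisson_counts_near_one(self, rng):
        counts = rng.poisson(5.0, 1000)
        spikes, trials = self._trials_with_counts(counts)
        ff = fano_factor(spikes, trials)
        se = np.sqrt(2.0 / (len(counts) - 1))
        assert abs(ff - 1.0) < 3 * se

    def test_invariant_to_trial_order(self, rng):
        counts = rng.poisson(4.0, 50)
        spikes, trials = self._trials_with_counts(counts)
        shuffled = trials.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert fano_factor(spikes, shuffled) == pytest.approx(
            fano_factor(spikes, trials)
        )

    def test_too_few_trials_nan(self):
        spikes, trials = self._trials_with_counts([2])
        assert np.isnan(fano_factor(spikes, trials))


class TestProportionModulated:
    def _result(self, modulated):
        from reprophys import ModulationResult

        return {
            "movement_initiation": ModulationResult(
                "movement_initiation",
                0.001 if modulated else (0.5 if modulated is not None else np.nan),
                modulated,
                1.0,
                50,
            )
        }

    def test_all_modulated(self):
        results = [self._result(True) for _ in range(6)]
        assert proportion_modulated(results, "movement_initiation") == 1.0

    def test_small_region_excluded(self):
        results = [self._result(True) for _ in range(3)]
        assert np.isnan(proportion_modulated(results, "movement_initiation"))

    def test_undetermined_excluded_from_denominator(self):
        results = [self._result(True), self._result(False)] + [
            self._result(None) for _ in range(3)
        ]
        assert proportion_modulated(results, "movement_initiation") == 0.5

    def test_known_responder_fraction_recovered(self):
        # 30% of units respond to movement; the recovered proportion sits
        # near 0.3 plus the ~5% false-positive rate among non-responders.
        trials = gen_trial_table(120, seed=7)
        dur = trials.feedback_time.iloc[-1] + 2
        moves = trials.first_move.to_numpy()
        results = []
        for i in range(60):
            if i < 18:
                spikes = gen_event_locked_train(
                    10.0, moves, lambda t: 12.0 * ((t >= 0) & (t < 0.2)), dur, seed=i
                )
            else:
                spikes = gen_spike_train(10.0, dur, seed=i)
            results.append(modulation_tests(spikes, trials))
        frac = proportion_modulated(results, "movement_initiation")
        assert 0.2 < frac < 0.48
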