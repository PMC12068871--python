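"""Generator contracts: refractory structure, contamination census,
amplitude truncation, trial-table structure, and population bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reprophys import (
    REGIONS,
    SynthConfig,
    gen_amplitudes,
    gen_lab_feature_values,
    gen_multilab_population,
    gen_spike_train,
    gen_trial_table,
)


class TestSpikeTrain:
    def test_zero_rate_is_empty(self):
        assert len(gen_spike_train(0.0, 10.0, seed=0)) == 0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gen_spike_train(-1.0, 10.0)
        with pytest.raises(ValueError):
            gen_spike_train(5.0, 0.0)
        with pytest.raises(ValueError):
            gen_spike_train(5.0, 10.0, contamination=1.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_uncontaminated_respects_refractory(self, seed):
        t = gen_spike_train(50.0, 120.0, refractory=0.002, contamination=0.0, seed=seed)
        assert np.all(np.diff(t) >= 0.002)

    def test_contaminated_isi_census_matches_renewal_expectation(self):
        # With base rate r and contaminating rate r*c/(1-c), an ISI is short
        # when the next event arrives within the refractory period: only
        # contamination can follow a clean spike, anything can follow a
        # contaminating spike. Weighting the two exponential tail
        # probabilities by the spike mix gives the expected short-ISI rate.
        rate, c, rp = 20.0, 0.2, 0.002
        contam_rate = rate * c / (1 - c)
        total = rate + contam_rate
        expected = (1 - c) * (1 - np.exp(-contam_rate * rp)) + c * (
            1 - np.exp(-total * rp)
        )
        fracs = []
        for seed in range(5):
            t = gen_spike_train(rate, 600.0, refractory=rp, contamination=c, seed=seed)
            fracs.append(np.mean(np.diff(t) < rp))
        assert abs(np.mean(fracs) - expected) < 0.004

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        rate=st.floats(0.0, 80.0),
        duration=st.floats(1.0, 50.0),
        seed=st.integers(0, 2**16),
    )
    def test_output_sorted_and_bounded(self, rate, duration, seed):
        t = gen_spike_train(rate, duration, contamination=0.1, seed=seed)
        assert np.all(np.diff(t) > 0)
        assert len(t) == 0 or (t[0] >= 0 and t[-1] <= duration)

    def test_determinism(self):
        a = gen_spike_train(30.0, 60.0, contamination=0.1, seed=7)
        b = gen_spike_train(30.0, 60.0, contamination=0.1, seed=7)
        np.testing.assert_array_equal(a, b)


class TestAmplitudes:
    def test_empty(self):
        assert len(gen_amplitudes(0, 100.0, 10.0, seed=0)) == 0

    def test_mean_within_three_standard_errors(self):
        a = gen_amplitudes(10000, 100.0, 10.0, seed=1)
        assert abs(a.mean() - 100.0) < 3 * 10.0 / np.sqrt(10000)

    def test_truncation_at_mean_keeps_upper_half(self):
        a = gen_amplitudes(10000, 100.0, 10.0, truncation=100.0, seed=2)
        assert a.min() >= 100.0
        # Binomial(10000, 0.5) within 4 sigma.
        assert abs(len(a) - 5000) < 4 * np.sqrt(10000 * 0.25)


class TestTrialTable:
    def test_single_trial_event_order(self):
        t = gen_trial_table(1, seed=0)
        assert len(t) == 1
        row = t.iloc[0]
        assert row.stim_on < row.first_move < row.feedback_time

    def test_biased_block_side_frequencies(self):
        t = gen_trial_table(3000, seed=3)
        biased = t[t.block_p_left == 0.2]
        assert len(biased) > 300
        frac_left = (biased.side == "left").mean()
        assert abs(frac_left - 0.2) < 4 * np.sqrt(0.2 * 0.8 / len(biased))

    def test_reaction_times_straddle_split_point(self):
        t = gen_trial_table(500, rt_mean=0.15, seed=4)
        assert (t.reaction_time < 0.15).any() and (t.reaction_time > 0.15).any()
        assert (t.reaction_time > 0).all()

    def test_contrasts_from_task_set(self):
        t = gen_trial_table(200, seed=5)
        assert set(t.contrast).issubset({0.0, 0.0625, 0.125, 0.25, 1.0})


class TestPopulation:
    def test_bookkeeping(self, small_population):
        assert len(small_population) == 4  # 4 labs x 1 mouse x 1 session
        labs = {s.lab_id for s in small_population}
        assert len(labs) == 4
        for s in small_population:
            assert len(s.units) == 3 * len(REGIONS)
            regions = {u.region for u in s.units}
            assert regions == set(REGIONS)

    def test_determinism_bit_identical(self):
        cfg = dict(
            seed=9,
            n_labs=2,
            mice_per_lab=1,
            units_per_region={r: 1 for r in REGIONS},
            n_trials=30,
            n_channels=16,
        )
        a = gen_multilab_population(SynthConfig(**cfg))
        b = gen_multilab_population(SynthConfig(**cfg))
        for sa, sb in zip(a, b):
            for ua, ub in zip(sa.units, sb.units):
                np.testing.assert_array_equal(ua.spike_times, ub.spike_times)
                np.testing.assert_array_equal(ua.amplitudes, ub.amplitudes)
            np.testing.assert_array_equal(sa.ap_rms_per_channel, sb.ap_rms_per_channel)

    def test_injected_rate_shift_dominates(self):
        base = dict(
            n_labs=3,
            mice_per_lab=1,
            units_per_region={r: 4 for r in REGIONS},
            n_trials=60,
            n_channels=16,
        )
        for seed in (0, 1):
            pop = gen_multilab_population(
                SynthConfig(
                    seed=seed, lab_effects={"lab_01": {"firing_rate": 10.0}}, **base
                )
            )
            means = {}
            for s in pop:
                rates = [u.n_spikes / s.duration for u in s.units]
                means.setdefault(s.lab_id, []).extend(rates)
            means = {k: np.mean(v) for k, v in means.items()}
            assert max(means, key=means.get) == "lab_01"

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SynthConfig(contamination=1.2)
        with pytest.raises(ValueError):
            SynthConfig(refractory=0.0)
        with pytest.raises(ValueError):
            SynthConfig(n_trials=-1)


class TestFeatureValues:
    def test_shapes_and_shift(self):
        v, l = gen_lab_feature_values(10, 4, seed=0)
        assert len(v) == 40 and len(np.unique(l)) == 10
        v2, l2 = gen_lab_feature_values(10, 4, seed=0, lab_shifts={3: 5.0})
        mask = l2 == "lab_03"
        np.testing.assert_allclose(v2[mask] - v[mask], 5.0)
        np.testing.assert_allclose(v2[~mask], v[~mask])
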