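"""Decimation-based rate equalization between conditions."""

import numpy as np
import pytest
from scipy import stats

from lipdcm.core import select_events, aligned_counts, mean_rate
from lipdcm.equalization import (
    DecimationPlan,
    decimate_spikes,
    equalize_by_attention,
    equalize_by_sample,
    pretest_ratio,
)
from lipdcm.synth import NeuronGenProfile, TaskConfig, generate_neuron_spikes, generate_trials
from lipdcm.selectivity import sliding_selectivity

from conftest import make_neuron, make_trial


def build_two_condition_neuron(rate_a_hz, rate_b_hz, n_each=8):
    """Deterministic neuron: evenly spaced spikes at the stated rate in the
    200 ms pre-test window (and during the test period) of every trial."""
    trials, spikes = [], []
    for i in range(2 * n_each):
        sample = "A" if i < n_each else "B"
        rate = rate_a_hz if sample == "A" else rate_b_hz
        trial = make_trial(i, sample=sample, stimuli=[(4, 1)])
        k_pre = int(rate * 0.2)  # spikes in [700, 900)
        k_test = int(rate * 0.45)  # spikes in [900, 1350)
        times = np.concatenate(
            [np.linspace(700, 900, k_pre, endpoint=False), np.linspace(900, 1350, k_test, endpoint=False)]
        )
        trials.append(trial)
        spikes.append(np.sort(times))
    return make_neuron(trials, spikes)


class TestPretestRatio:
    def test_worked_example_20_vs_25(self):
        neuron = build_two_condition_neuron(20, 25)
        plan = pretest_ratio(neuron, "by_sample")
        assert plan.ratio == pytest.approx(1.25)
        assert plan.target_condition == "B"
        assert plan.removal_fraction == pytest.approx(0.2)

    def test_equal_rates_ratio_one(self):
        neuron = build_two_condition_neuron(20, 20)
        plan = pretest_ratio(neuron, "by_sample")
        assert plan.ratio == pytest.approx(1.0)
        assert plan.removal_fraction == pytest.approx(0.0)

    def test_ratio_by_direct_division(self):
        neuron = build_two_condition_neuron(10, 40)
        plan = pretest_ratio(neuron, "by_sample")
        assert plan.ratio == pytest.approx(4.0)
        assert plan.removal_fraction == pytest.approx(0.75)

    def test_zero_rate_one_condition_flagged_no_decimation(self):
        neuron = build_two_condition_neuron(0, 20)
        plan = pretest_ratio(neuron, "by_sample")
        assert plan.flagged
        assert plan.removal_fraction == 0.0
        out = decimate_spikes(neuron, plan)
        assert all(
            np.array_equal(a.spike_times_ms, b.spike_times_ms)
            for a, b in zip(neuron.spikes, out.spikes)
        )

    def test_zero_rate_both_conditions_error(self):
        neuron = build_two_condition_neuron(0, 0)
        with pytest.raises(ValueError, match="nothing to equate"):
            pretest_ratio(neuron, "by_sample")


class TestDecimation:
    def _random_neuron(self, seed=0, n_trials=120):
        trials = generate_trials(TaskConfig(n_trials=n_trials), seed)
        p = NeuronGenProfile(baseline_hz=25, amp_identity_hz=0, amp_match_hz=0, sample_memory_gain=0.4)
        return generate_neuron_spikes(p, trials, seed + 1)

    def test_subset_property_and_nontarget_conservation(self):
        neuron = self._random_neuron()
        plan = pretest_ratio(neuron, "by_sample", seed=3)
        out = decimate_spikes(neuron, plan)
        for trial, before, after in zip(neuron.trials, neuron.spikes, out.spikes):
            assert np.all(np.isin(after.spike_times_ms, before.spike_times_ms))
            if trial.sample_identity != plan.target_condition:
                assert np.array_equal(after.spike_times_ms, before.spike_times_ms)

    def test_zero_fraction_is_identity(self):
        neuron = self._random_neuron()
        plan = DecimationPlan("by_sample", 1.0, 0.0, "A", seed=0)
        out = decimate_spikes(neuron, plan)
        assert all(
            np.array_equal(a.spike_times_ms, b.spike_times_ms)
            for a, b in zip(neuron.spikes, out.spikes)
        )

    def test_fraction_out_of_range_rejected(self):
        neuron = self._random_neuron()
        with pytest.raises(ValueError):
            decimate_spikes(neuron, DecimationPlan("by_sample", 10.0, 1.0, "A", seed=0))

    def test_bernoulli_retention_matches_binomial_law(self):
        # one long synthetic trial with 100k test-period spikes
        trial = make_trial(0, sample="A", stimuli=[(4, 1)])
        times = np.linspace(900, 1350, 100_000, endpoint=False)
        neuron = make_neuron([trial, make_trial(1, sample="B", stimuli=[(4, 1)])], [times, [1000.0]])
        plan = DecimationPlan("by_sample", 4 / 3, 0.25, "A", seed=42)
        out = decimate_spikes(neuron, plan)
        kept = out.spikes[0].spike_times_ms.size
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 100_000, 0.75)
        assert lo <= kept <= hi
        assert np.all(np.isin(out.spikes[0].spike_times_ms, times))

    def test_exact_mode_removes_exact_count(self):
        neuron = self._random_neuron()
        plan = pretest_ratio(neuron, "by_sample", seed=5, mode="exact")
        total_before = 0
        for trial, train in zip(neuron.trials, neuron.spikes):
            if trial.sample_identity != plan.target_condition:
                continue
            t = train.spike_times_ms
            for e in trial.events:
                if not e.is_distractor:
                    total_before += int(np.sum((t >= e.onset_ms) & (t < e.offset_ms)))
        out = decimate_spikes(neuron, plan)
        removed = sum(a.spike_times_ms.size - b.spike_times_ms.size for a, b in zip(neuron.spikes, out.spikes))
        assert removed == round(plan.removal_fraction * total_before)

    def test_determinism_given_seed(self):
        neuron = self._random_neuron()
        out1, plan1 = equalize_by_sample(neuron, seed=9)
        out2, plan2 = equalize_by_sample(neuron, seed=9)
        assert plan1 == plan2
        assert all(
            np.array_equal(a.spike_times_ms, b.spike_times_ms)
            for a, b in zip(out1.spikes, out2.spikes)
        )


class TestEqualizeBySample:
    def test_memoryless_neuron_nearly_untouched(self):
        trials = generate_trials(TaskConfig(n_trials=300), 20)
        p = NeuronGenProfile(baseline_hz=25, amp_identity_hz=0, amp_match_hz=0, sample_memory_gain=0.0)
        neuron = generate_neuron_spikes(p, trials, 21)
        _, plan = equalize_by_sample(neuron, seed=22)
        assert plan.removal_fraction < 0.06

    def test_decimation_is_unbiased_on_average(self):
        # expected post-decimation pre-test ratio equals 1 over repeats
        trials = generate_trials(TaskConfig(n_trials=400), 23)
        p = NeuronGenProfile(baseline_hz=20, amp_identity_hz=0, amp_match_hz=0, sample_memory_gain=0.25)
        neuron = generate_neuron_spikes(p, trials, 24)
        plan = pretest_ratio(neuron, "by_sample", seed=0)

        def post_ratio(out):
            # pre-test windows of positions >= 2 lie inside the decimated test period
            rates = {}
            for cond in ("A", "B"):
                evs = [
                    ev for ev in select_events(out, positions=[2, 3, 4])
                    if ev.trial.sample_identity == cond
                ]
                rates[cond] = mean_rate(aligned_counts(out, evs, (-200.0, 0.0)), 200.0)
            return rates[plan.target_condition] / rates["A" if plan.target_condition == "B" else "B"]

        ratios = []
        for rep in range(60):
            plan_rep = DecimationPlan(
                plan.grouping, plan.ratio, plan.removal_fraction, plan.target_condition, seed=rep
            )
            ratios.append(post_ratio(decimate_spikes(neuron, plan_rep)))
        assert abs(np.mean(ratios) - 1.0) < 0.04

    def test_removes_spurious_pre_onset_identity_selectivity(self):
        # memory-only neuron: elevated rate on preferred-sample trials mimics
        # identity selectivity before stimulus onset; equalization removes it
        # the pooled identity comparison dilutes the memory confound (each
        # stimulus appears in both samples), so a strong gain and many
        # trials are needed for the raw pre-onset effect to be detectable
        trials = generate_trials(TaskConfig(n_trials=700), 25)
        p = NeuronGenProfile(baseline_hz=15, amp_identity_hz=0, amp_match_hz=0, sample_memory_gain=1.0)
        neuron = generate_neuron_spikes(p, trials, 26)
        raw = sliding_selectivity(neuron, "identity", step_ms=5.0)
        eq, plan = equalize_by_sample(neuron, seed=27)
        cor = sliding_selectivity(eq, "identity", step_ms=5.0)
        pre = cor.times_ms < -50  # windows fully before onset
        assert plan.removal_fraction > 0.4  # gain 2x between samples
        assert raw.p_value[pre].min() < 0.001  # spurious pre-onset effect
        assert np.abs(raw.roc[pre] - 0.5).max() > 0.08
        assert not np.any(cor.significant[pre])
        assert np.all(np.abs(cor.roc[pre] - 0.5) < 0.1)
        assert np.abs(cor.roc[pre] - 0.5).max() < np.abs(raw.roc[pre] - 0.5).max()


class TestEqualizeByAttention:
    def _neuron(self, gain, seed=30, n_trials=400):
        trials = generate_trials(TaskConfig(n_trials=n_trials), seed)
        p = NeuronGenProfile(
            baseline_hz=20, amp_identity_hz=0, amp_match_hz=0, attention_gain=gain
        )
        return generate_neuron_spikes(p, trials, seed + 1)

    def test_unity_gain_is_noop_within_noise(self):
        _, plan = equalize_by_attention(self._neuron(1.0), seed=31)
        assert plan.removal_fraction < 0.07

    def test_gain_removed_at_large_n(self):
        neuron = self._neuron(1.5, n_trials=800)
        out, plan = equalize_by_attention(neuron, seed=32)
        assert plan.target_condition == "IN"
        post = pretest_ratio(out, "by_attention", seed=33)
        assert post.ratio < 1.07

    def test_first_position_exclusion_matters(self):
        # delay-period (pre-first-test) rate differs from test-period rate:
        # ratio with the exclusion uses visually driven activity only
        trials = generate_trials(TaskConfig(n_trials=600), 34)
        p = NeuronGenProfile(
            baseline_hz=10, amp_identity_hz=0, amp_match_hz=0,
            attention_gain=1.5, color_slope_hz_per_step=2.0,
        )
        neuron = generate_neuron_spikes(p, trials, 35)
        with_excl = pretest_ratio(neuron, "by_attention")
        evs_all = select_events(neuron)
        rates = {}
        for cond in ("IN", "OUT"):
            evs = [ev for ev in evs_all if ev.trial.attention == cond]
            rates[cond] = mean_rate(aligned_counts(neuron, evs, (-200.0, 0.0)), 200.0)
        naive = max(rates.values()) / min(rates.values())
        assert with_excl.ratio != pytest.approx(naive, rel=1e-6)

    def test_one_location_data_rejected(self):
        trials = generate_trials(TaskConfig(variant="one_location", n_trials=50), 36)
        p = NeuronGenProfile(amp_identity_hz=0, amp_match_hz=0)
        neuron = generate_neuron_spikes(p, trials, 37)
        with pytest.raises(ValueError, match="two-location"):
            equalize_by_attention(neuron, seed=38)
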