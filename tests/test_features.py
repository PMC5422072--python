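"""Additivity decomposition, tuning measurement, and attention shifts."""

import numpy as np
import pandas as pd
import pytest

from lipdcm.features import (
    ConditionResponses,
    additivity_index,
    color_shift,
    color_slope,
    condition_responses,
    correlate_profiles,
    direction_shift,
    preferred_direction,
    sliding_additivity,
)
from lipdcm.synth import NeuronGenProfile, TaskConfig, generate_neuron_spikes, generate_trials

from conftest import make_neuron, make_trial


def _cr(T, CM, DM, OT):
    return ConditionResponses(T=T, CM=CM, DM=DM, OT=OT, window=(100, 350), n_events={})


class TestAdditivityIndex:
    def test_zero_for_any_additive_construction(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(1000):
            C, D, I = rng.uniform(0.1, 20.0, 3)
            idx = additivity_index(_cr(T=C + D + I, CM=C + I, DM=D + I, OT=I))
            worst = max(worst, abs(idx))
        assert worst < 1e-12

    def test_exactly_zero_on_dyadic_components(self):
        # components on a 1/256 grid: float arithmetic is exact
        rng = np.random.default_rng(1)
        for _ in range(1000):
            C, D, I = rng.integers(1, 4096, 3) / 256.0
            assert additivity_index(_cr(C + D + I, C + I, D + I, I)) == 0.0

    def test_super_additive_arithmetic_example(self):
        assert additivity_index(_cr(T=3.0, CM=1.5, DM=1.5, OT=1.0)) == pytest.approx(1.0)

    def test_invariant_to_common_baseline_shift(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            T, CM, DM, OT = rng.uniform(0, 10, 4)
            k = rng.uniform(-5, 5)
            assert additivity_index(_cr(T + k, CM + k, DM + k, OT + k)) == pytest.approx(
                additivity_index(_cr(T, CM, DM, OT)), abs=1e-9
            )

    def test_multiplicative_conjunction_term_scores_positive(self):
        # target = C + D + I + gamma*C*D with gamma > 0
        rng = np.random.default_rng(3)
        for _ in range(200):
            C, D, I = rng.uniform(0.5, 5.0, 3)
            idx = additivity_index(_cr(C + D + I + 0.3 * C * D, C + I, D + I, I))
            assert idx > 0


def _tuning_neuron(counts_by_color=None, counts_by_direction=None, sample="A", start_id=0):
    """Deterministic neuron: one test event per stimulus, with an exact
    spike count in the 100-350 ms response window."""
    trials, spikes = [], []
    i = start_id
    if counts_by_color is not None:
        # colors 1..8 paired with neutral directions (not 270 or 90)
        for c in range(1, 9):
            for d in (1, 2, 5):
                n_spk = counts_by_color[c - 1]
                trials.append(make_trial(i, sample=sample, stimuli=[(c, d)]))
                spikes.append(np.linspace(1000, 1250, n_spk, endpoint=False))
                i += 1
    if counts_by_direction is not None:
        for d in range(1, 9):
            for c in (3, 4, 5):
                n_spk = counts_by_direction[d - 1]
                trials.append(make_trial(i, sample=sample, stimuli=[(c, d)]))
                spikes.append(np.linspace(1000, 1250, n_spk, endpoint=False))
                i += 1
    return make_neuron(trials, spikes)


class TestColorTuning:
    def test_slope_recovers_closed_form_least_squares(self):
        # mean counts 1..8 over the 250 ms window -> 4 Hz per color step
        neuron = _tuning_neuron(counts_by_color=list(range(1, 9)))
        assert color_slope(neuron, "A") == pytest.approx(4.0)

    def test_flat_tuning_zero_slope(self):
        neuron = _tuning_neuron(counts_by_color=[3] * 8)
        assert color_slope(neuron, "A") == pytest.approx(0.0)

    def test_reversed_axis_negates_slope(self):
        up = _tuning_neuron(counts_by_color=list(range(1, 9)))
        down = _tuning_neuron(counts_by_color=list(range(8, 0, -1)))
        assert color_slope(up, "A") == pytest.approx(-color_slope(down, "A"))

    def test_identical_tuning_both_samples_zero_shift(self):
        a = _tuning_neuron(counts_by_color=list(range(1, 9)), sample="A")
        b = _tuning_neuron(counts_by_color=list(range(1, 9)), sample="B", start_id=100)
        both = make_neuron(
            a.trials + b.trials,
            [a.spike_train(t.trial_id).spike_times_ms for t in a.trials]
            + [b.spike_train(t.trial_id).spike_times_ms for t in b.trials],
        )
        assert color_shift(both) == pytest.approx(0.0)

    def test_attraction_toward_relevant_color_is_negative(self):
        # generator displaces tuning toward the cued color
        trials = generate_trials(TaskConfig(n_trials=500), 70)
        p = NeuronGenProfile(
            baseline_hz=15, amp_identity_hz=0, amp_match_hz=0,
            color_slope_hz_per_step=2.0, fba_color_shift=2.0,
        )
        neuron = generate_neuron_spikes(p, trials, 71)
        assert color_shift(neuron) < 0

    def test_shift_antisymmetric_under_sample_swap(self):
        a = _tuning_neuron(counts_by_color=list(range(1, 9)), sample="A")
        b = _tuning_neuron(counts_by_color=[8, 6, 5, 4, 4, 3, 2, 1], sample="B", start_id=100)
        both = make_neuron(
            a.trials + b.trials,
            [a.spike_train(t.trial_id).spike_times_ms for t in a.trials]
            + [b.spike_train(t.trial_id).spike_times_ms for t in b.trials],
        )
        swapped_a = _tuning_neuron(counts_by_color=[8, 6, 5, 4, 4, 3, 2, 1], sample="A")
        swapped_b = _tuning_neuron(counts_by_color=list(range(1, 9)), sample="B", start_id=100)
        swapped = make_neuron(
            swapped_a.trials + swapped_b.trials,
            [swapped_a.spike_train(t.trial_id).spike_times_ms for t in swapped_a.trials]
            + [swapped_b.spike_train(t.trial_id).spike_times_ms for t in swapped_b.trials],
        )
        assert color_shift(both) == pytest.approx(-color_shift(swapped))


class TestDirectionTuning:
    def test_flat_tuning_undefined(self):
        neuron = _tuning_neuron(counts_by_direction=[4] * 8)
        assert preferred_direction(neuron, "A") is None

    def test_single_direction_response(self):
        counts = [0] * 8
        counts[4] = 6  # direction index 5 -> 180 degrees
        neuron = _tuning_neuron(counts_by_direction=counts)
        assert preferred_direction(neuron, "A") == pytest.approx(180.0)

    def test_cosine_tuning_recovers_peak_by_trig_identity(self):
        # counts proportional to 1 + cos(theta - 90): vector sum points at 90
        angles = np.deg2rad(np.arange(8) * 45.0)
        counts = np.round(8 * (1 + np.cos(angles - np.pi / 2))).astype(int)
        neuron = _tuning_neuron(counts_by_direction=list(counts))
        assert preferred_direction(neuron, "A") == pytest.approx(90.0, abs=1.5)

    def test_shift_sign_positive_toward_relevant_direction(self):
        # preferred 80 deg under sample A (relevant 90... here relevant for A
        # is 270) -- construct attraction: under A the peak sits nearer 270
        angles = np.deg2rad(np.arange(8) * 45.0)
        toward = np.round(8 * (1 + np.cos(angles - np.deg2rad(250)))).astype(int)
        away = np.round(8 * (1 + np.cos(angles - np.deg2rad(200)))).astype(int)
        a = _tuning_neuron(counts_by_direction=list(toward), sample="A")
        b = _tuning_neuron(counts_by_direction=list(away), sample="B", start_id=100)
        both = make_neuron(
            a.trials + b.trials,
            [a.spike_train(t.trial_id).spike_times_ms for t in a.trials]
            + [b.spike_train(t.trial_id).spike_times_ms for t in b.trials],
        )
        shift = direction_shift(both)
        assert shift is not None and shift > 0

    def test_shift_magnitude_bounded_by_180(self):
        rng = np.random.default_rng(4)
        for s in range(10):
            ca = list(rng.integers(0, 9, 8))
            cb = list(rng.integers(0, 9, 8))
            a = _tuning_neuron(counts_by_direction=ca, sample="A")
            b = _tuning_neuron(counts_by_direction=cb, sample="B", start_id=100)
            both = make_neuron(
                a.trials + b.trials,
                [a.spike_train(t.trial_id).spike_times_ms for t in a.trials]
                + [b.spike_train(t.trial_id).spike_times_ms for t in b.trials],
            )
            shift = direction_shift(both)
            if shift is not None:
                assert abs(shift) <= 180.0


class TestConditionResponses:
    def _neuron(self, **kw):
        trials = generate_trials(TaskConfig(n_trials=500), 72)
        p = NeuronGenProfile(amp_identity_hz=0, amp_match_hz=0, baseline_hz=12, **kw)
        return generate_neuron_spikes(p, trials, 73)

    def test_untuned_neuron_equal_responses(self):
        cr = condition_responses(self._neuron())
        vals = [cr.T, cr.CM, cr.DM, cr.OT]
        assert max(vals) - min(vals) < 0.25 * np.mean(vals)

    def test_pure_color_coder_gradient(self):
        # color tuning only, with attention displacement: sharing the
        # relevant color keeps the response near the target's
        cr = condition_responses(
            self._neuron(color_slope_hz_per_step=3.0, fba_color_shift=1.5, pref_identity="B")
        )
        assert abs(cr.CM - cr.T) < 0.25 * cr.T
        assert cr.T > cr.DM
        assert cr.OT <= cr.T * 1.05

    def test_match_generator_is_super_additive(self):
        trials = generate_trials(TaskConfig(n_trials=400), 74)
        p = NeuronGenProfile(continuum_w=-1.0, amp_match_hz=30, baseline_hz=10, rt_sd_ms=20)
        neuron = generate_neuron_spikes(p, trials, 75)
        cr = condition_responses(neuron)
        assert additivity_index(cr) > 0.3
        assert cr.T > max(cr.CM, cr.DM, cr.OT)

    def test_empty_class_reported_by_name(self):
        trials = [make_trial(i, stimuli=[(4, 4)]) for i in range(10)]
        neuron = make_neuron(trials, [[1000.0]] * 10)
        with pytest.raises(ValueError, match="class T"):
            condition_responses(neuron, pref="A")


class TestProfileCorrelations:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)})
        r, p = correlate_profiles(df, "x", "y")
        assert r == pytest.approx(1.0)

    def test_independent_fields_near_zero(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=1000), "y": rng.normal(size=1000)})
        r, _ = correlate_profiles(df, "x", "y")
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="variance"):
            correlate_profiles(df, "x", "y")

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="pairs"):
            correlate_profiles(df, "x", "y")

    def test_sliding_additivity_window_shape(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"vdi": rng.uniform(-1, 1, 60), "additivity_index": rng.normal(size=60)})
        out = sliding_additivity(df, width=31)
        assert len(out) == 60
        assert out["additivity_sliding_mean"].notna().sum() == 60 - 30
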