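"""Randomized spike decimation to equate firing rates between conditions.

Sample-identity memory and space-based attention both elevate a neuron's
rate in one condition before test stimuli appear, which masquerades as
stimulus selectivity in sliding comparisons.  Before selectivity analyses,
the higher-rate condition's test-period spike trains are therefore thinned
so that pre-test rates match: the removal fraction is estimated from the
ratio of mean rates in the 200 ms window preceding test-stimulus onsets
(e.g. 20 vs 25 spikes/s gives a ratio of 1.25 and removal of 1/5 of the
higher condition's test-period spikes).

Thinning is independent Bernoulli per spike by default, which preserves
Poisson statistics; an exact-count mode (remove ``round(f * N)`` uniformly
chosen spikes) is available for sensitivity checks.  The ratio is estimated
from correct trials only; decimation never touches the lower-rate
condition and only removes spikes, never adds or moves them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import AlignedEvent, NeuronRecording, SpikeTrain, aligned_counts, mean_rate, select_events

Grouping = Literal["by_sample", "by_attention"]

PRETEST_WINDOW = (-200.0, 0.0)


@dataclass(frozen=True)
class DecimationPlan:
    grouping: Grouping
    ratio: float  # higher / lower pre-test rate
    removal_fraction: float  # 1 - lower / higher
    target_condition: str  # the higher-rate condition label
    seed: int
    flagged: bool = False  # one condition had zero rate; no decimation applied
    mode: Literal["bernoulli", "exact"] = "bernoulli"


def _condition_of(trial, grouping: Grouping) -> str:
    return trial.sample_identity if grouping == "by_sample" else trial.attention


def _pretest_events(neuron: NeuronRecording, grouping: Grouping) -> list[AlignedEvent]:
    # For attention grouping, windows preceding the first test stimulus fall
    # in the delay epoch and are excluded so the ratio reflects responses to
    # visual stimuli.
    positions = None
    if grouping == "by_attention":
        max_pos = 4 if neuron.task_variant == "two_location" else 3
        positions = list(range(2, max_pos + 1))
    return select_events(neuron, positions=positions)


def pretest_ratio(
    neuron: NeuronRecording,
    grouping: Grouping,
    seed: int = 0,
    mode: Literal["bernoulli", "exact"] = "bernoulli",
) -> DecimationPlan:
    """Estimate the pre-test rate ratio between the two conditions and
    build the decimation plan for the higher-rate one."""
    if grouping == "by_attention" and neuron.task_variant == "one_location":
        raise ValueError("attention equalization requires two-location data (no attention OUT)")
    events = _pretest_events(neuron, grouping)
    conds = sorted({_condition_of(ev.trial, grouping) for ev in events})
    if len(conds) < 2:
        raise ValueError(f"need events in both conditions for grouping {grouping}")
    rates = {}
    for cond in conds:
        evs = [ev for ev in events if _condition_of(ev.trial, grouping) == cond]
        if not evs:
            raise ValueError(f"no qualifying pre-test windows in condition {cond}")
        counts = aligned_counts(neuron, evs, PRETEST_WINDOW)
        rates[cond] = mean_rate(counts, PRETEST_WINDOW[1] - PRETEST_WINDOW[0])
    (lo_cond, lo), (hi_cond, hi) = sorted(rates.items(), key=lambda kv: kv[1])
    if hi == 0.0:
        raise ValueError("zero pre-test rate in both conditions: nothing to equate")
    if lo == 0.0:
        return DecimationPlan(grouping, float("inf"), 0.0, hi_cond, seed, flagged=True, mode=mode)
    return DecimationPlan(
        grouping=grouping,
        ratio=hi / lo,
        removal_fraction=1.0 - lo / hi,
        target_condition=hi_cond,
        seed=seed,
        mode=mode,
    )


def decimate_spikes(neuron: NeuronRecording, plan: DecimationPlan) -> NeuronRecording:
    """Thin the target condition's test-period spikes per the plan.

    Each spike emitted during a test-stimulus presentation in the target
    condition is retained with probability ``1 - removal_fraction``
    (Bernoulli mode) or ``round(f * N)`` spikes are removed uniformly
    across the condition (exact mode).  All other spikes are untouched.
    """
    if not (0.0 <= plan.removal_fraction < 1.0):
        raise ValueError(f"removal_fraction {plan.removal_fraction} outside [0, 1)")
    if plan.flagged or plan.removal_fraction == 0.0:
        return neuron
    rng = np.random.default_rng(plan.seed)

    # locate test-period spikes per target-condition trial
    masks: list[tuple[int, np.ndarray]] = []  # (train index, boolean mask of candidates)
    for i, trial in enumerate(neuron.trials):
        if _condition_of(trial, plan.grouping) != plan.target_condition:
            masks.append((i, None))
            continue
        times = neuron.spikes[i].spike_times_ms
        in_test = np.zeros(times.size, dtype=bool)
        for e in trial.events:
            if e.is_distractor:
                continue
            in_test |= (times >= e.onset_ms) & (times < e.offset_ms)
        masks.append((i, in_test))

    if plan.mode == "bernoulli":
        keep_fn = lambda n: rng.random(n) >= plan.removal_fraction
        removals = None
    else:
        total = sum(int(m.sum()) for _, m in masks if m is not None)
        n_remove = int(round(plan.removal_fraction * total))
        chosen = rng.choice(total, size=n_remove, replace=False) if n_remove else np.empty(0, int)
        removed_flat = np.zeros(total, dtype=bool)
        removed_flat[chosen] = True
        removals = removed_flat
        offset = 0

    new_trains = []
    for i, mask in masks:
        train = neuron.spikes[i]
        if mask is None or not mask.any():
            new_trains.append(train)
            continue
        keep = np.ones(train.spike_times_ms.size, dtype=bool)
        idx = np.flatnonzero(mask)
        if plan.mode == "bernoulli":
            keep[idx] = keep_fn(idx.size)
        else:
            keep[idx] = ~removals[offset : offset + idx.size]
            offset += idx.size
        new_trains.append(SpikeTrain(trial_id=train.trial_id, spike_times_ms=train.spike_times_ms[keep]))
    return neuron.with_spikes(new_trains)


def equalize_by_sample(
    neuron: NeuronRecording, seed: int, mode: Literal["bernoulli", "exact"] = "bernoulli"
) -> tuple[NeuronRecording, DecimationPlan]:
    """Equate pre-test rates between sample A and sample B trials."""
    plan = pretest_ratio(neuron, "by_sample", seed=seed, mode=mode)
    return decimate_spikes(neuron, plan), plan


def equalize_by_attention(
    neuron: NeuronRecording, seed: int, mode: Literal["bernoulli", "exact"] = "bernoulli"
) -> tuple[NeuronRecording, DecimationPlan]:
    """Equate pre-test rates between attention IN and OUT trials
    (two-location data only; the delay-epoch window preceding the first
    test stimulus is excluded from the ratio)."""
    plan = pretest_ratio(neuron, "by_attention", seed=seed, mode=mode)
    return decimate_spikes(neuron, plan), plan
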