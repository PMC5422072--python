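"""Shared fixtures: small synthetic populations and hand-built recordings."""

import logging

import numpy as np
import pytest

from lipdcm.core import (
    NeuronRecording,
    SpikeTrain,
    StimulusID,
    TestEvent,
    TrialRecord,
    match_class_of,
)
from lipdcm.synth import TaskConfig, continuum_profiles, generate_population

logging.disable(logging.WARNING)


def make_trial(
    trial_id,
    sample="A",
    stimuli=((4, 1),),
    attention="IN",
    variant="two_location",
    outcome="correct_reject",
    rt_ms=None,
    is_catch=None,
    epoch=450.0,
):
    """Hand-built trial: one test event per (color, direction) pair, no
    distractors, events starting after sample + delay epochs."""
    events = []
    for pos, (c, d) in enumerate(stimuli, start=1):
        stim = StimulusID(c, d)
        events.append(
            TestEvent(
                stimulus=stim,
                location="IN" if attention == "IN" else "OUT",
                onset_ms=2 * epoch + (pos - 1) * epoch,
                duration_ms=epoch,
                match_class=match_class_of(stim, sample),
                position_in_sequence=pos,
            )
        )
    if is_catch is None:
        is_catch = not any(e.match_class == "target" for e in events)
    return TrialRecord(
        trial_id=trial_id,
        sample_identity=sample,
        attention=attention,
        task_variant=variant,
        events=tuple(events),
        is_catch=is_catch,
        outcome=outcome,
        rt_ms=rt_ms,
    )


def make_neuron(trials, spike_times_per_trial, neuron_id="h0", monkey_id="S"):
    spikes = [
        SpikeTrain(trial_id=t.trial_id, spike_times_ms=np.asarray(s, dtype=float))
        for t, s in zip(trials, spike_times_per_trial)
    ]
    rts = [t.rt_ms for t in trials if t.outcome == "hit"]
    return NeuronRecording(
        neuron_id=neuron_id,
        monkey_id=monkey_id,
        task_variant=trials[0].task_variant,
        trials=list(trials),
        spikes=spikes,
        session_mean_rt_ms=float(np.mean(rts)) if rts else float("nan"),
    )


@pytest.fixture(scope="session")
def small_population():
    cfg = TaskConfig(n_trials=150)
    profiles = continuum_profiles(6, seed=11)
    dataset, report = generate_population(cfg, profiles, seed=12)
    return dataset, report


@pytest.fixture(scope="session")
def one_neuron(small_population):
    return small_population[0].neurons[0]
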