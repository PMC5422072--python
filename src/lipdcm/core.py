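"""Core data model for trial-aligned LIP spike recordings.

The delayed-conjunction-matching (DCM) task presents a sample stimulus
(a conjunction of one of eight colors and one of eight motion directions),
a delay, then a sequence of test stimuli; the subject releases a lever when
a test stimulus matches the remembered sample in both features.  All
analysis code in this package operates on the containers defined here:
trials with labelled test events, per-trial spike trains, and per-neuron
recordings grouped into population datasets.

Times are in milliseconds from trial start; analysis windows are half-open
``[t0, t1)`` and, once aligned, relative to test-stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

Location = Literal["IN", "OUT"]
SampleID = Literal["A", "B"]
TaskVariant = Literal["two_location", "one_location"]
MatchClass = Literal["target", "opposite_target", "color_match", "direction_match", "other"]
Outcome = Literal["hit", "miss", "false_alarm", "correct_reject"]

N_COLORS = 8
N_DIRECTIONS = 8
DIRECTION_STEP_DEG = 360.0 / N_DIRECTIONS


class ValidationError(ValueError):
    """A container violates one of the documented invariants."""


class SchemaError(ValueError):
    """A file is missing a required field or has an unrecognized layout."""


@dataclass(frozen=True)
class StimulusID:
    """A color x motion-direction conjunction.

    ``color_index`` runs 1 (yellow) to 8 (red); ``direction_index`` runs
    1 to 8 over directions evenly spaced by 45 degrees, with angle
    ``(direction_index - 1) * 45`` measured counterclockwise from rightward.
    """

    color_index: int
    direction_index: int

    def __post_init__(self) -> None:
        if not (1 <= self.color_index <= N_COLORS):
            raise ValidationError(f"color_index {self.color_index} outside [1, {N_COLORS}]")
        if not (1 <= self.direction_index <= N_DIRECTIONS):
            raise ValidationError(
                f"direction_index {self.direction_index} outside [1, {N_DIRECTIONS}]"
            )

    @property
    def direction_angle_deg(self) -> float:
        return (self.direction_index - 1) * DIRECTION_STEP_DEG


#: The two sample conjunctions: A = yellow dots moving downward (270 deg),
#: B = red dots moving upward (90 deg).
SAMPLE_STIMULI: dict[SampleID, StimulusID] = {
    "A": StimulusID(color_index=1, direction_index=7),
    "B": StimulusID(color_index=8, direction_index=3),
}

#: Relevant feature values per sample identity.
RELEVANT_COLOR: dict[SampleID, int] = {s: stim.color_index for s, stim in SAMPLE_STIMULI.items()}
RELEVANT_DIRECTION_DEG: dict[SampleID, float] = {
    s: stim.direction_angle_deg for s, stim in SAMPLE_STIMULI.items()
}


def all_stimuli() -> list[StimulusID]:
    """The full 8 x 8 = 64 conjunction universe."""
    return [
        StimulusID(c, d)
        for c in range(1, N_COLORS + 1)
        for d in range(1, N_DIRECTIONS + 1)
    ]


def match_class_of(stimulus: StimulusID, sample: SampleID) -> MatchClass:
    """Classify a test stimulus relative to the current sample.

    ``target`` matches the sample in both features; ``opposite_target`` is
    the other sample conjunction; ``color_match`` shares only the relevant
    color, ``direction_match`` only the relevant direction.
    """
    own = SAMPLE_STIMULI[sample]
    other = SAMPLE_STIMULI["B" if sample == "A" else "A"]
    if stimulus == own:
        return "target"
    if stimulus == other:
        return "opposite_target"
    if stimulus.color_index == own.color_index:
        return "color_match"
    if stimulus.direction_index == own.direction_index:
        return "direction_match"
    return "other"


@dataclass(frozen=True)
class TestEvent:
    stimulus: StimulusID
    location: Location
    onset_ms: float
    duration_ms: float
    match_class: MatchClass
    position_in_sequence: int
    is_distractor: bool = False

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass(frozen=True)
class TrialRecord:
    trial_id: int
    sample_identity: SampleID
    attention: Location
    task_variant: TaskVariant
    events: tuple[TestEvent, ...]
    is_catch: bool
    outcome: Outcome
    rt_ms: float | None = None

    @property
    def test_events(self) -> tuple[TestEvent, ...]:
        return tuple(e for e in self.events if not e.is_distractor)

    @property
    def target_event(self) -> TestEvent | None:
        for e in self.test_events:
            if e.match_class == "target":
                return e
        return None

    @property
    def end_ms(self) -> float:
        if not self.events:
            return 0.0
        return max(e.offset_ms for e in self.events)


@dataclass(frozen=True)
class SpikeTrain:
    trial_id: int
    spike_times_ms: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times_ms, dtype=float)
        object.__setattr__(self, "spike_times_ms", times)


@dataclass
class NeuronRecording:
    neuron_id: str
    monkey_id: str
    task_variant: TaskVariant
    trials: list[TrialRecord]
    spikes: list[SpikeTrain]
    session_mean_rt_ms: float

    def __post_init__(self) -> None:
        self._by_trial = {s.trial_id: s for s in self.spikes}

    def spike_train(self, trial_id: int) -> SpikeTrain:
        return self._by_trial[trial_id]

    def with_spikes(self, spikes: list[SpikeTrain]) -> "NeuronRecording":
        return NeuronRecording(
            neuron_id=self.neuron_id,
            monkey_id=self.monkey_id,
            task_variant=self.task_variant,
            trials=self.trials,
            spikes=spikes,
            session_mean_rt_ms=self.session_mean_rt_ms,
        )


@dataclass
class PopulationDataset:
    neurons: list[NeuronRecording]
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# validation

def validate_trial(trial: TrialRecord) -> None:
    targets = [e for e in trial.test_events if e.match_class == "target"]
    if trial.is_catch and targets:
        raise ValidationError(f"trial {trial.trial_id}: catch trial contains a target event")
    if trial.outcome == "hit":
        if len(targets) != 1:
            raise ValidationError(f"trial {trial.trial_id}: hit without exactly one target")
        if trial.rt_ms is None:
            raise ValidationError(f"trial {trial.trial_id}: hit without reaction time")
    if trial.outcome in ("miss", "correct_reject") and trial.rt_ms is not None:
        raise ValidationError(f"trial {trial.trial_id}: no-response outcome carries an RT")
    if trial.task_variant == "one_location":
        if any(e.is_distractor for e in trial.events):
            raise ValidationError(
                f"trial {trial.trial_id}: distractors in one-location variant"
            )
    max_pos = 4 if trial.task_variant == "two_location" else 3
    for e in trial.test_events:
        if not (1 <= e.position_in_sequence <= max_pos):
            raise ValidationError(
                f"trial {trial.trial_id}: sequence position {e.position_in_sequence} "
                f"outside [1, {max_pos}]"
            )
        expect = match_class_of(e.stimulus, trial.sample_identity)
        if e.match_class != expect:
            raise ValidationError(
                f"trial {trial.trial_id}: event labelled {e.match_class} but stimulus "
                f"is {expect} for sample {trial.sample_identity}"
            )


def validate_neuron(neuron: NeuronRecording, strict: bool = True) -> None:
    if len(neuron.trials) != len(neuron.spikes):
        raise ValidationError(
            f"neuron {neuron.neuron_id}: {len(neuron.trials)} trials but "
            f"{len(neuron.spikes)} spike trains"
        )
    trial_ids = {t.trial_id for t in neuron.trials}
    if trial_ids != {s.trial_id for s in neuron.spikes}:
        raise ValidationError(f"neuron {neuron.neuron_id}: trial/spike id mismatch")
    for trial in neuron.trials:
        if strict:
            validate_trial(trial)
        times = neuron.spike_train(trial.trial_id).spike_times_ms
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValidationError(
                    f"neuron {neuron.neuron_id} trial {trial.trial_id}: unsorted spikes"
                )
            if times[0] < 0 or times[-1] > trial.end_ms:
                raise ValidationError(
                    f"neuron {neuron.neuron_id} trial {trial.trial_id}: spike outside "
                    f"[0, {trial.end_ms}]"
                )
    rts = [t.rt_ms for t in neuron.trials if t.outcome == "hit"]
    if strict and rts:
        if not np.isclose(neuron.session_mean_rt_ms, float(np.mean(rts))):
            raise ValidationError(
                f"neuron {neuron.neuron_id}: session_mean_rt_ms inconsistent with hits"
            )


def validate_dataset(dataset: PopulationDataset, strict: bool = True) -> None:
    ids = [n.neuron_id for n in dataset.neurons]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate neuron_ids in dataset")
    for neuron in dataset.neurons:
        validate_neuron(neuron, strict=strict)


# ---------------------------------------------------------------------------
# event selection and alignment

@dataclass(frozen=True)
class AlignedEvent:
    """A test event tagged with its parent trial, for windowed analyses."""

    trial: TrialRecord
    event: TestEvent

    @property
    def onset_ms(self) -> float:
        return self.event.onset_ms


def select_events(
    neuron: NeuronRecording,
    *,
    locations: Sequence[Location] | None = None,
    match_classes: Sequence[MatchClass] | None = None,
    stimuli: Sequence[StimulusID] | None = None,
    samples: Sequence[SampleID] | None = None,
    positions: Sequence[int] | None = None,
    outcomes: Sequence[Outcome] | None = ("hit", "correct_reject"),
    include_distractors: bool = False,
    predicate: Callable[[TrialRecord, TestEvent], bool] | None = None,
) -> list[AlignedEvent]:
    """Select test events across trials by condition labels.

    By default only correct trials (hits and correct rejections) qualify,
    matching the convention of analyzing correct trials only.
    """
    stim_set = set(stimuli) if stimuli is not None else None
    out: list[AlignedEvent] = []
    for trial in neuron.trials:
        if outcomes is not None and trial.outcome not in outcomes:
            continue
        if samples is not None and trial.sample_identity not in samples:
            continue
        for e in trial.events:
            if e.is_distractor and not include_distractors:
                continue
            if locations is not None and e.location not in locations:
                continue
            if match_classes is not None and e.match_class not in match_classes:
                continue
            if stim_set is not None and e.stimulus not in stim_set:
                continue
            if positions is not None and e.position_in_sequence not in positions:
                continue
            if predicate is not None and not predicate(trial, e):
                continue
            out.append(AlignedEvent(trial=trial, event=e))
    return out


def aligned_counts(
    neuron: NeuronRecording,
    events: Sequence[AlignedEvent],
    window: tuple[float, float],
    *,
    check_bounds: bool = True,
) -> np.ndarray:
    """Spike counts per event in the half-open window ``[t0, t1)`` relative
    to each event's onset.  A spike exactly at the upper bound is excluded.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError(f"window [{t0}, {t1}) is not well-ordered")
    if check_bounds:
        offending = [
            ev
            for ev in events
            if ev.onset_ms + t0 < 0 or ev.onset_ms + t1 > ev.trial.end_ms + 1e-9
        ]
        if offending:
            ids = [(ev.trial.trial_id, ev.event.position_in_sequence) for ev in offending]
            raise ValueError(
                f"window [{t0}, {t1}) extends beyond trial span for events "
                f"(trial_id, position): {ids[:10]}"
            )
    counts = np.empty(len(events), dtype=np.int64)
    for i, ev in enumerate(events):
        times = neuron.spike_train(ev.trial.trial_id).spike_times_ms
        lo = np.searchsorted(times, ev.onset_ms + t0, side="left")
        hi = np.searchsorted(times, ev.onset_ms + t1, side="left")
        counts[i] = hi - lo
    return counts


def sliding_counts(
    neuron: NeuronRecording,
    events: Sequence[AlignedEvent],
    centers_ms: np.ndarray,
    window_ms: float,
) -> np.ndarray:
    """Matrix of spike counts, shape ``(n_events, n_centers)``, where entry
    ``(i, j)`` counts spikes of event *i* in ``[c_j - w/2, c_j + w/2)``
    relative to onset.  Windows may extend past trial bounds (zero-padded),
    which is appropriate for sliding traces near trial edges.
    """
    centers = np.asarray(centers_ms, dtype=float)
    half = window_ms / 2.0
    lo_edges = centers - half
    hi_edges = centers + half
    out = np.empty((len(events), centers.size), dtype=np.int64)
    for i, ev in enumerate(events):
        rel = neuron.spike_train(ev.trial.trial_id).spike_times_ms - ev.onset_ms
        lo = np.searchsorted(rel, lo_edges, side="left")
        hi = np.searchsorted(rel, hi_edges, side="left")
        out[i] = hi - lo
    return out


def mean_rate(counts: np.ndarray, window_ms: float) -> float:
    """Mean firing rate in spikes/s from per-event counts in a window."""
    counts = np.asarray(counts)
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if counts.size == 0:
        raise ValueError("mean rate undefined for zero events")
    return float(np.mean(counts)) / window_ms * 1000.0


def binned_rate(
    neuron: NeuronRecording,
    event: AlignedEvent,
    t_range: tuple[float, float],
) -> np.ndarray:
    """Per-ms spike indicator trace aligned to an event onset, in spikes/s."""
    t0, t1 = t_range
    n = int(round(t1 - t0))
    rel = neuron.spike_train(event.trial.trial_id).spike_times_ms - event.onset_ms
    edges = t0 + np.arange(n + 1, dtype=float)
    hist = np.diff(np.searchsorted(rel, edges, side="left"))
    return hist.astype(float) * 1000.0


def smooth_trace(trace: np.ndarray, sigma_ms: float = 15.0) -> np.ndarray:
    """Gaussian smoothing of a 1-ms-binned trace.

    The kernel has unit area and is truncated at +/- 4 sigma; near the trace
    edges the output is renormalized by the in-range kernel mass so that a
    constant trace is returned unchanged everywhere.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    trace = np.asarray(trace, dtype=float)
    radius = int(np.ceil(4 * sigma_ms))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma_ms) ** 2)
    kernel /= kernel.sum()
    num = np.convolve(trace, kernel, mode="same")
    den = np.convolve(np.ones_like(trace), kernel, mode="same")
    return num / den
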