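"""Synthetic delayed-conjunction-matching task and spike generator.

Generates trial schedules for the two task variants (two-location: 450 ms
sample/delay/test epochs, 1-4 test stimuli, 20% catch trials; one-location:
550 ms epochs, 1-3 tests, 25% catch), reaction times, and
inhomogeneous-Poisson spike trains for model neurons spanning a continuum
from purely identity-selective (``w = +1``) to purely match-selective
(``w = -1``) coding.

The generator is the test bed for every analysis stage: each profile field
is ground truth that a downstream estimator should recover (onset
latencies, attention gain, tuning shifts, RT coupling), and the report
returned by :func:`generate_population` records all of it.

Response onsets are step functions with a 20 ms linear rise; rates are
floored at zero after summing all terms; spikes are drawn from a Poisson
count in each 1 ms bin with uniform placement within the bin, which is an
exact inhomogeneous Poisson process for the piecewise-constant rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .core import (
    RELEVANT_COLOR,
    RELEVANT_DIRECTION_DEG,
    SAMPLE_STIMULI,
    NeuronRecording,
    PopulationDataset,
    SampleID,
    SpikeTrain,
    StimulusID,
    TaskVariant,
    TestEvent,
    TrialRecord,
    all_stimuli,
    match_class_of,
    validate_dataset,
)

RT_FLOOR_MS = 150.0


@dataclass(frozen=True)
class TaskConfig:
    """Task schedule parameters.

    Defaults reproduce the two-location variant: 450 ms epochs, up to four
    test stimuli, 20% catch trials, even sample and attention splits, and
    target positions biased toward the first test period (the first
    position is over-represented relative to the later ones).  Outcomes of
    completed trials split roughly 90% hits / 6% misses / 4% false alarms.
    """

    variant: TaskVariant = "two_location"
    n_trials: int = 400
    epoch_ms: float | None = None  # sample = delay = test duration
    max_tests: int | None = None
    catch_fraction: float | None = None
    target_position_bias: tuple[float, ...] | None = None
    p_hit: float = 0.90
    p_miss: float = 0.06
    p_false_alarm: float = 0.04
    p_opposite_target: float = 0.30  # non-target test slot is the opposite sample

    def resolved(self) -> "TaskConfig":
        two = self.variant == "two_location"
        epoch = self.epoch_ms if self.epoch_ms is not None else (450.0 if two else 550.0)
        max_tests = self.max_tests if self.max_tests is not None else (4 if two else 3)
        catch = self.catch_fraction if self.catch_fraction is not None else (0.20 if two else 0.25)
        bias = self.target_position_bias
        if bias is None:
            # over-present first-position targets (first weight doubled)
            raw = np.array([2.0] + [1.0] * (max_tests - 1))
            bias = tuple(raw / raw.sum())
        if len(bias) != max_tests:
            raise ValueError(f"target_position_bias length {len(bias)} != max_tests {max_tests}")
        b = np.asarray(bias, dtype=float)
        if np.any(b < 0) or not np.isclose(b.sum(), 1.0):
            raise ValueError("target_position_bias must be nonnegative and sum to 1")
        if not (0.0 <= catch < 1.0):
            raise ValueError("catch_fraction must be in [0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        return TaskConfig(
            variant=self.variant,
            n_trials=self.n_trials,
            epoch_ms=epoch,
            max_tests=max_tests,
            catch_fraction=catch,
            target_position_bias=tuple(b),
            p_hit=self.p_hit,
            p_miss=self.p_miss,
            p_false_alarm=self.p_false_alarm,
            p_opposite_target=self.p_opposite_target,
        )


@dataclass(frozen=True)
class NeuronGenProfile:
    """Ground-truth generative parameters for one model neuron.

    ``continuum_w`` places the neuron on the identity-to-match continuum:
    +1 is purely identity-coding, -1 purely match-coding, and intermediate
    values mix both with effective amplitudes
    ``amp_identity * (1 + w) / 2`` and ``amp_match * (1 - w) / 2``
    (a monotone map from ``w`` to the expected visuo-decision index).
    """

    neuron_id: str = "n0"
    monkey_id: str = "S"
    baseline_hz: float = 10.0
    continuum_w: float = 1.0
    amp_identity_hz: float = 20.0
    amp_match_hz: float = 20.0
    latency_identity_ms: float = 100.0
    latency_match_ms: float = 190.0
    pref_identity: SampleID = "A"
    attention_gain: float = 1.0  # multiplicative rate gain, attention IN vs OUT
    bilateral_match: bool = False  # match response also for targets outside the RF
    sample_memory_gain: float = 0.0  # rate modulation on preferred-sample trials
    color_slope_hz_per_step: float = 0.0
    direction_amp_hz: float = 0.0
    direction_kappa: float = 2.0
    direction_pref_deg: float = 0.0
    fba_color_shift: float = 0.0  # slope displacement toward the relevant color
    fba_direction_shift_deg: float = 0.0  # preferred-direction pull toward relevant direction
    cp_coupling: float = 0.0  # share of RT variance coupled to match-onset jitter
    rt_mean_ms: float = 400.0
    rt_sd_ms: float = 50.0
    rise_ms: float = 20.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.continuum_w <= 1.0):
            raise ValueError("continuum_w must lie in [-1, 1]")
        if not (0.0 <= self.cp_coupling <= 1.0):
            raise ValueError("cp_coupling must lie in [0, 1]")
        if self.attention_gain < 0:
            raise ValueError("attention_gain must be nonnegative")
        if self.rt_sd_ms < 0:
            raise ValueError("rt_sd_ms must be nonnegative")

    @property
    def amp_identity_eff(self) -> float:
        return self.amp_identity_hz * (1.0 + self.continuum_w) / 2.0

    @property
    def amp_match_eff(self) -> float:
        return self.amp_match_hz * (1.0 - self.continuum_w) / 2.0


# ---------------------------------------------------------------------------
# trial schedules

def _draw_nontarget(rng: np.random.Generator, sample: SampleID, p_ot: float,
                    universe: list[StimulusID]) -> StimulusID:
    own = SAMPLE_STIMULI[sample]
    other = SAMPLE_STIMULI["B" if sample == "A" else "A"]
    if rng.random() < p_ot:
        return other
    while True:
        stim = universe[rng.integers(len(universe))]
        if stim != own and stim != other:
            return stim


def generate_trials(cfg: TaskConfig, seed: int) -> list[TrialRecord]:
    """Draw a trial schedule (no reaction times yet; see
    :func:`attach_rts`).  Non-catch trials contain exactly one target at a
    position drawn from the position bias; earlier test slots hold
    opposite-target or other conjunctions; catch trials run the full test
    sequence without a target.
    """
    cfg = cfg.resolved()
    rng = np.random.default_rng(seed)
    universe = all_stimuli()
    two = cfg.variant == "two_location"
    epoch = cfg.epoch_ms
    trials: list[TrialRecord] = []
    positions = np.arange(1, cfg.max_tests + 1)
    for trial_id in range(cfg.n_trials):
        sample: SampleID = "A" if rng.random() < 0.5 else "B"
        attention = ("IN" if rng.random() < 0.5 else "OUT") if two else "IN"
        is_catch = rng.random() < cfg.catch_fraction

        if is_catch:
            n_tests = cfg.max_tests
            target_pos = None
        else:
            target_pos = int(rng.choice(positions, p=cfg.target_position_bias))
            n_tests = target_pos

        stimuli: list[StimulusID] = []
        for pos in range(1, n_tests + 1):
            if target_pos is not None and pos == target_pos:
                stimuli.append(SAMPLE_STIMULI[sample])
            else:
                stimuli.append(_draw_nontarget(rng, sample, cfg.p_opposite_target, universe))

        if is_catch:
            outcome = "false_alarm" if rng.random() < cfg.p_false_alarm else "correct_reject"
            fa_possible = n_tests >= 1
        else:
            u = rng.random()
            if u < cfg.p_hit:
                outcome = "hit"
            elif u < cfg.p_hit + cfg.p_miss:
                outcome = "miss"
            else:
                outcome = "false_alarm"
            fa_possible = target_pos is not None and target_pos > 1
            if outcome == "false_alarm" and not fa_possible:
                outcome = "miss"  # no pre-target slot to respond to

        fa_pos: int | None = None
        if outcome == "false_alarm":
            hi = n_tests if is_catch else target_pos - 1
            fa_pos = int(rng.integers(1, hi + 1))
            stimuli = stimuli[:fa_pos]  # trial aborted at the response
            n_tests = fa_pos

        test_loc = "IN" if attention == "IN" else "OUT"
        events: list[TestEvent] = []
        for pos, stim in enumerate(stimuli, start=1):
            onset = 2 * epoch + (pos - 1) * epoch  # after sample + delay
            events.append(
                TestEvent(
                    stimulus=stim,
                    location=test_loc,
                    onset_ms=onset,
                    duration_ms=epoch,
                    match_class=match_class_of(stim, sample),
                    position_in_sequence=pos,
                )
            )
            if two:
                dstim = universe[rng.integers(len(universe))]
                events.append(
                    TestEvent(
                        stimulus=dstim,
                        location="IN" if test_loc == "OUT" else "OUT",
                        onset_ms=onset,
                        duration_ms=epoch,
                        match_class=match_class_of(dstim, sample),
                        position_in_sequence=pos,
                        is_distractor=True,
                    )
                )
        trials.append(
            TrialRecord(
                trial_id=trial_id,
                sample_identity=sample,
                attention=attention,
                task_variant=cfg.variant,
                events=tuple(events),
                is_catch=is_catch,
                outcome=outcome,
                rt_ms=None,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# reaction times

def generate_rt(
    profile: NeuronGenProfile,
    shared_jitter_ms: float,
    rng: np.random.Generator,
) -> float:
    """Reaction time (ms from target onset) for one hit trial.

    ``shared_jitter_ms`` is the same latent Gaussian draw that shifts the
    trial's match-response onset; ``cp_coupling`` sets the fraction of RT
    standard deviation it contributes, with the rest independent noise, so
    total RT variance is ``rt_sd_ms ** 2`` regardless of coupling.  RTs are
    floored at 150 ms.
    """
    c = profile.cp_coupling
    indep = np.sqrt(max(0.0, 1.0 - c * c)) * profile.rt_sd_ms * rng.standard_normal()
    rt = profile.rt_mean_ms + c * shared_jitter_ms + indep
    return float(max(RT_FLOOR_MS, rt))


# ---------------------------------------------------------------------------
# spike trains

def _ramp(t: np.ndarray, onset: float, rise: float) -> np.ndarray:
    """Unit step at ``onset`` with a linear rise of width ``rise``."""
    if rise <= 0:
        return (t >= onset).astype(float)
    return np.clip((t - onset) / rise, 0.0, 1.0)


def _circ_diff_deg(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Signed circular difference a - b in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def _shift_toward(angle: float, toward: float, amount: float) -> float:
    """Move ``angle`` by ``amount`` degrees along the shorter arc to ``toward``."""
    d = float(_circ_diff_deg(toward, angle))
    step = np.sign(d) * min(abs(d), amount)
    return float((angle + step) % 360.0)


def trial_rate(
    profile: NeuronGenProfile,
    trial: TrialRecord,
    shared_jitter_ms: float = 0.0,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) in 1 ms bins over the whole trial.

    Sum of a baseline (modulated by space-based attention and sample
    memory), an identity term stepping on after preferred-identity test
    stimuli, a match term stepping on after targets (jittered by the
    RT-coupled latent draw), and color/direction feature tuning terms with
    feature-based-attention displacement toward the current sample's
    relevant feature values.  The summed rate is floored at zero.
    """
    n = int(round(trial.end_ms))
    t = np.arange(n, dtype=float) + 0.5
    rate = np.full(n, profile.baseline_hz, dtype=float)

    sample = trial.sample_identity
    rel_color = RELEVANT_COLOR[sample]
    rel_dir = RELEVANT_DIRECTION_DEG[sample]
    # FBA displacement of tuning: slope shifted down when yellow (color 1)
    # is relevant and up when red (color 8) is relevant; preferred direction
    # pulled along the shorter arc toward the relevant direction.
    slope = profile.color_slope_hz_per_step + (
        -profile.fba_color_shift / 2.0 if rel_color == 1 else profile.fba_color_shift / 2.0
    )
    pref_dir = _shift_toward(profile.direction_pref_deg, rel_dir, profile.fba_direction_shift_deg)
    pref_stim = SAMPLE_STIMULI[profile.pref_identity]

    for e in trial.events:
        if e.is_distractor:
            continue  # distractor influence is absorbed by the location gating
        in_event = (t >= e.onset_ms) & (t < e.offset_ms)
        if not np.any(in_event):
            continue
        if e.location == "IN":
            vis = _ramp(t, e.onset_ms + profile.latency_identity_ms, profile.rise_ms) * in_event
            if e.stimulus == pref_stim:
                rate += profile.amp_identity_eff * vis
            rate += slope * (e.stimulus.color_index - 4.5) * vis
            if profile.direction_amp_hz != 0.0:
                dd = np.deg2rad(_circ_diff_deg(e.stimulus.direction_angle_deg, pref_dir))
                tune = np.exp(profile.direction_kappa * (np.cos(dd) - 1.0))
                rate += profile.direction_amp_hz * float(tune) * vis
        if e.match_class == "target" and (e.location == "IN" or profile.bilateral_match):
            onset = e.onset_ms + profile.latency_match_ms + shared_jitter_ms
            rate += profile.amp_match_eff * _ramp(t, onset, profile.rise_ms) * in_event
    # attention and sample-memory gains are multiplicative on the whole
    # response, so decimation by the pre-test rate ratio removes them
    if trial.attention == "IN":
        rate *= profile.attention_gain
    if trial.sample_identity == profile.pref_identity:
        rate *= 1.0 + profile.sample_memory_gain
    return np.maximum(rate, 0.0)


def _spikes_from_rate(rate_hz: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(rate_hz * 1e-3)
    idx = np.repeat(np.arange(counts.size), counts)
    times = idx + rng.random(idx.size)
    return np.sort(times)


def generate_neuron_spikes(
    profile: NeuronGenProfile,
    trials: Sequence[TrialRecord],
    seed: int,
) -> NeuronRecording:
    """Simulate one neuron over a trial schedule.

    Attaches reaction times to hit and false-alarm trials (hit RTs share a
    latent jitter with the neuron's match-response onset, implementing the
    choice-probability coupling) and draws spike trains from the
    inhomogeneous Poisson rate of :func:`trial_rate`.
    """
    rng = np.random.default_rng(seed)
    out_trials: list[TrialRecord] = []
    spike_trains: list[SpikeTrain] = []
    hit_rts: list[float] = []
    for trial in trials:
        jitter = 0.0
        rt = None
        if trial.outcome == "hit":
            jitter = profile.rt_sd_ms * rng.standard_normal()
            rt = generate_rt(profile, jitter, rng)
            hit_rts.append(rt)
        elif trial.outcome == "false_alarm":
            rt = float(max(RT_FLOOR_MS,
                           profile.rt_mean_ms + profile.rt_sd_ms * rng.standard_normal()))
        trial = TrialRecord(
            trial_id=trial.trial_id,
            sample_identity=trial.sample_identity,
            attention=trial.attention,
            task_variant=trial.task_variant,
            events=trial.events,
            is_catch=trial.is_catch,
            outcome=trial.outcome,
            rt_ms=rt,
        )
        rate = trial_rate(profile, trial, shared_jitter_ms=jitter)
        spike_trains.append(
            SpikeTrain(trial_id=trial.trial_id, spike_times_ms=_spikes_from_rate(rate, rng))
        )
        out_trials.append(trial)
    mean_rt = float(np.mean(hit_rts)) if hit_rts else float("nan")
    return NeuronRecording(
        neuron_id=profile.neuron_id,
        monkey_id=profile.monkey_id,
        task_variant=trials[0].task_variant if trials else "two_location",
        trials=out_trials,
        spikes=spike_trains,
        session_mean_rt_ms=mean_rt,
    )


# ---------------------------------------------------------------------------
# populations

def sample_profiles(
    n: int,
    seed: int,
    *,
    w: Sequence[float] | None = None,
    **overrides,
) -> list[NeuronGenProfile]:
    """Draw ``n`` profiles spanning the identity-match continuum.

    ``w`` fixes each neuron's continuum position; by default it is drawn
    uniformly on [-1, 1].  Preferred identities alternate A/B.  Any
    profile field can be overridden for the whole population, or per
    neuron by passing a sequence of length ``n``.
    """
    rng = np.random.default_rng(seed)
    ws = np.asarray(w, dtype=float) if w is not None else rng.uniform(-1, 1, n)
    if ws.size != n:
        raise ValueError("w must have length n")
    profiles = []
    for i in range(n):
        kw = {}
        for key, val in overrides.items():
            if isinstance(val, (list, tuple, np.ndarray)) and not isinstance(val, str):
                kw[key] = val[i]
            else:
                kw[key] = val
        kw.setdefault("pref_identity", "A" if i % 2 == 0 else "B")
        profiles.append(
            NeuronGenProfile(
                neuron_id=f"n{i:03d}",
                continuum_w=float(ws[i]),
                **kw,
            )
        )
    return profiles


def continuum_profiles(
    n: int,
    seed: int,
    *,
    w: Sequence[float] | None = None,
    baseline_hz: float = 10.0,
    color_slope_max: float = 2.0,
    direction_amp_max: float = 8.0,
    tuning_floor: float = 0.3,
    amp_match_hz: float = 35.0,
    cp_coupling_match: float = 0.8,
    fba_color_shift_max: float = 1.2,
    fba_direction_shift_max_deg: float = 25.0,
    sample_memory_gain: float = 0.25,
    attention_gain: float = 1.4,
    **overrides,
) -> list[NeuronGenProfile]:
    """Profiles for the canonical visuo-decision continuum population.

    Identity selectivity is carried by *feature tuning* — a color slope and
    unimodal direction tuning peaked at the preferred sample's features,
    scaled by ``(1 + w) / 2`` down to a floor so every cell keeps some
    sensory tuning — rather than by the exact-conjunction step term: a
    feature-tuned neuron discriminates the two sample conjunctions (which
    sit at opposite ends of both feature axes) by linearly summing feature
    signals, whereas an exact-conjunction detector is super-additive by
    construction.  Match selectivity is the non-sensory step term scaled by
    ``(1 - w) / 2``, which enters target responses only and makes
    match-dominated cells super-additive.  RT coupling and
    feature-based-attention tuning shifts load on the match-dominated end
    of the continuum, mirroring the observation that decision covariates
    and attention shifts concentrate in decision-related neurons.
    """
    ws = np.asarray(w, dtype=float) if w is not None else np.linspace(-1, 1, n)
    if ws.size != n:
        raise ValueError("w must have length n")
    profiles = []
    for i in range(n):
        wi = float(ws[i])
        ident = max(tuning_floor, (1.0 + wi) / 2.0)
        match = (1.0 - wi) / 2.0
        pref: SampleID = "A" if i % 2 == 0 else "B"
        # color runs yellow (1, sample A) to red (8, sample B): an A-preferring
        # cell's response falls with color rank, a B-preferring cell's rises
        slope_sign = -1.0 if pref == "A" else 1.0
        kw = dict(
            neuron_id=f"n{i:03d}",
            baseline_hz=baseline_hz,
            continuum_w=wi,
            amp_identity_hz=0.0,
            amp_match_hz=amp_match_hz,
            pref_identity=pref,
            color_slope_hz_per_step=slope_sign * color_slope_max * ident,
            direction_amp_hz=direction_amp_max * ident,
            direction_pref_deg=RELEVANT_DIRECTION_DEG[pref],
            fba_color_shift=fba_color_shift_max * match,
            fba_direction_shift_deg=fba_direction_shift_max_deg * match,
            cp_coupling=cp_coupling_match if wi < 0 else 0.0,
            sample_memory_gain=sample_memory_gain,
            attention_gain=attention_gain,
        )
        for key, val in overrides.items():
            if isinstance(val, (list, tuple, np.ndarray)) and not isinstance(val, str):
                kw[key] = val[i]
            else:
                kw[key] = val
        profiles.append(NeuronGenProfile(**kw))
    return profiles


def generate_population(
    cfg: TaskConfig,
    profiles: Sequence[NeuronGenProfile],
    seed: int,
) -> tuple[PopulationDataset, pd.DataFrame]:
    """Simulate a population, one independent session per neuron.

    Returns the dataset and a ground-truth report: one row per neuron with
    every generative parameter, the realized per-condition trial counts,
    and the per-neuron seed, sufficient to regenerate the dataset exactly.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    ids = [p.neuron_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate neuron_ids in profiles")
    root = np.random.default_rng(seed)
    rows = []
    neurons = []
    for profile in profiles:
        trial_seed = int(root.integers(2**31 - 1))
        spike_seed = int(root.integers(2**31 - 1))
        trials = generate_trials(cfg, trial_seed)
        neuron = generate_neuron_spikes(profile, trials, spike_seed)
        neurons.append(neuron)
        row = asdict(profile)
        row.update(
            trial_seed=trial_seed,
            spike_seed=spike_seed,
            n_trials=len(trials),
            n_hits=sum(t.outcome == "hit" for t in trials),
            n_catch=sum(t.is_catch for t in trials),
            n_sample_A=sum(t.sample_identity == "A" for t in trials),
            n_attention_in=sum(t.attention == "IN" for t in trials),
        )
        rows.append(row)
    task_info = asdict(cfg.resolved())
    task_info["target_position_bias"] = [float(x) for x in task_info["target_position_bias"]]
    dataset = PopulationDataset(
        neurons=neurons,
        provenance={"source": "synthetic", "seed": int(seed), "task": task_info},
    )
    validate_dataset(dataset)
    return dataset, pd.DataFrame(rows)
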