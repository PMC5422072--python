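"""Behavioral summaries, false-alarm maps, and choice probability.

*Choice probability* here is the across-trial Pearson correlation, at each
millisecond after target onset, between a trial's smoothed z-scored firing
rate and that trial's manual reaction time.  A match-driven neuron whose
response onset covaries with the behavioral response shows a negative
correlation: on fast-RT trials the response ramps earlier, so the rate in
the pre-response epoch is higher.

Qualifying trials are hits in which the sample was the neuron's preferred
stimulus, restricted to targets at sequence positions 2 and later —
first-position targets are over-represented by the task schedule and
would otherwise induce an artefactual rate-RT correlation.

Two normalization axes are supported.  The default z-scores each time
point across trials (the standard choice-probability convention): the
correlation then isolates trial-to-trial rate fluctuations around the
mean response, and an onset that arrives earlier on fast-RT trials yields
a clean negative correlation.  The alternative z-scores each trial's rate
across time, which removes per-trial additive offsets and gain but also
rescales response transients: an early onset produces a longer plateau
whose normalized height is lower, and the two effects largely cancel in a
window that spans both — useful as a robustness check against slow
excitability drifts, not as the primary statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    N_COLORS,
    N_DIRECTIONS,
    AlignedEvent,
    NeuronRecording,
    TrialRecord,
    binned_rate,
    smooth_trace,
)
from .selectivity import VDI_WINDOW, preferred_identity_of

logger = logging.getLogger(__name__)


@dataclass
class ChoiceProbabilityTrace:
    times_ms: np.ndarray
    r: np.ndarray
    n_trials: int
    summary_r: float
    degenerate: np.ndarray  # time points with zero across-trial variance


def behavior_summary(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Outcome fractions per attention condition.

    Correct trials (hits and correct rejections of catch trials) are
    grouped under ``correct``; with misses and false alarms the three
    fractions sum to one.  Fixation breaks are not modelled.
    """
    if not trials:
        raise ValueError("no trials")
    rows = []
    for attention in sorted({t.attention for t in trials}):
        grp = [t for t in trials if t.attention == attention]
        n = len(grp)
        correct = sum(t.outcome in ("hit", "correct_reject") for t in grp)
        miss = sum(t.outcome == "miss" for t in grp)
        fa = sum(t.outcome == "false_alarm" for t in grp)
        rows.append(
            dict(
                attention=attention,
                n_trials=n,
                correct=correct / n,
                miss=miss / n,
                false_alarm=fa / n,
            )
        )
    return pd.DataFrame(rows)


def false_alarm_map(trials: Sequence[TrialRecord]) -> dict[tuple[str, str], np.ndarray]:
    """8 x 8 false-alarm fraction grids keyed by (location, attention).

    Rows are direction index, columns color index.  Each cell is the
    fraction of presentations of that conjunction (at that location, in
    that attention condition) that drew a false-alarm response; the
    triggering stimulus of a false-alarm trial is the last test event.
    """
    presented: dict[tuple[str, str], np.ndarray] = {}
    responded: dict[tuple[str, str], np.ndarray] = {}
    for t in trials:
        for e in t.events:
            key = (e.location, t.attention)
            presented.setdefault(key, np.zeros((N_DIRECTIONS, N_COLORS)))
            responded.setdefault(key, np.zeros((N_DIRECTIONS, N_COLORS)))
            presented[key][e.stimulus.direction_index - 1, e.stimulus.color_index - 1] += 1
        if t.outcome == "false_alarm" and t.test_events:
            trigger = t.test_events[-1]
            key = (trigger.location, t.attention)
            responded[key][trigger.stimulus.direction_index - 1, trigger.stimulus.color_index - 1] += 1
    out = {}
    for key in presented:
        with np.errstate(invalid="ignore", divide="ignore"):
            grid = np.where(presented[key] > 0, responded[key] / presented[key], 0.0)
        out[key] = grid
    return out


def target_position_counts(trials: Sequence[TrialRecord], max_position: int) -> np.ndarray:
    counts = np.zeros(max_position)
    for t in trials:
        te = t.target_event
        if te is not None:
            counts[te.position_in_sequence - 1] += 1
    return counts


def target_position_anova(
    sessions: Sequence[Sequence[TrialRecord]], max_position: int = 4
) -> tuple[np.ndarray, float, float]:
    """Counts of target presentations by sequence position per session and
    a one-way ANOVA across positions (sessions as observations)."""
    if len(sessions) < 2:
        raise ValueError("need at least two sessions")
    counts = np.array([target_position_counts(s, max_position) for s in sessions])
    groups = [counts[:, j] for j in range(max_position)]
    if len(groups) < 2:
        raise ValueError("need at least two sequence positions")
    grand = np.concatenate(groups)
    if np.allclose(grand, grand[0]):
        return counts, 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return counts, float(f), float(p)


def choice_probability(
    neuron: NeuronRecording,
    t_range: tuple[float, float] | None = None,
    sigma_ms: float = 15.0,
    summary_window: tuple[float, float] = VDI_WINDOW,
    min_trials: int = 10,
    normalize: str = "per_time",
) -> ChoiceProbabilityTrace:
    """Per-millisecond correlation between smoothed z-scored rate (aligned
    to target onset) and reaction time over qualifying hit trials.

    ``normalize``: ``per_time`` (default) z-scores each time point across
    trials; ``per_trial`` z-scores each trial's trace across time (see
    module docstring for the tradeoff)."""
    pref = preferred_identity_of(neuron)
    if t_range is None:
        dur = 450.0 if neuron.task_variant == "two_location" else 550.0
        t_range = (0.0, dur)
    qualifying: list[tuple[AlignedEvent, float]] = []
    for trial in neuron.trials:
        if trial.outcome != "hit" or trial.sample_identity != pref:
            continue
        te = trial.target_event
        if te is None or te.position_in_sequence < 2:
            continue
        qualifying.append((AlignedEvent(trial=trial, event=te), trial.rt_ms))
    if len(qualifying) < min_trials:
        raise ValueError(
            f"only {len(qualifying)} qualifying trials (need >= {min_trials})"
        )
    rts = np.array([rt for _, rt in qualifying])
    rates = np.stack(
        [smooth_trace(binned_rate(neuron, ev, t_range), sigma_ms) for ev, _ in qualifying]
    )
    if normalize == "per_trial":
        mu_t = rates.mean(axis=1, keepdims=True)
        sd_t = rates.std(axis=1, keepdims=True)
        flat_trials = (sd_t == 0).ravel()
        z = np.where(sd_t == 0, 0.0, (rates - mu_t) / np.where(sd_t == 0, 1.0, sd_t))
    elif normalize == "per_time":
        mu = rates.mean(axis=0)
        sd = rates.std(axis=0)
        flat_trials = np.zeros(rates.shape[0], dtype=bool)
        z = np.where(sd == 0, 0.0, (rates - mu) / np.where(sd == 0, 1.0, sd))
    else:
        raise ValueError(f"unknown normalization: {normalize}")
    # Pearson r across trials per time point
    zc = z - z.mean(axis=0)
    denom = np.sqrt((zc**2).sum(axis=0))
    degenerate = denom == 0
    if degenerate.any() or flat_trials.any():
        logger.info(
            "neuron %s: %d degenerate time points, %d flat trials",
            neuron.neuron_id,
            int(degenerate.sum()),
            int(flat_trials.sum()),
        )
    rt_c = rts - rts.mean()
    rt_norm = np.sqrt((rt_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (zc.T @ rt_c) / (denom * rt_norm)
    r[degenerate] = 0.0
    times = t_range[0] + np.arange(rates.shape[1], dtype=float)
    sel = (times >= summary_window[0]) & (times <= summary_window[1])
    return ChoiceProbabilityTrace(
        times_ms=times,
        r=r,
        n_trials=len(qualifying),
        summary_r=float(r[sel].mean()),
        degenerate=degenerate,
    )


def cp_vdi_correlation(profiles: pd.DataFrame, exclude_bilateral: bool = False) -> tuple[float, float]:
    """Pearson correlation between each neuron's summary choice-probability
    r and its VDI; optionally excluding bilaterally match-selective
    neurons (robustness rerun)."""
    from .features import correlate_profiles

    df = profiles
    if exclude_bilateral and "laterality_class" in df.columns:
        df = df[df["laterality_class"] != "bilateral"]
    return correlate_profiles(df, "cp_summary_r", "vdi")
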