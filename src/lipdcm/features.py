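"""Conjunction coding: additivity decomposition, tuning, attention shifts.

A target stimulus carries the relevant color, the relevant direction, and
irrelevant information shared by all stimuli.  Writing the responses as
``T = C + D + I`` (target), ``CM = C + I`` (color-match: relevant color
with an irrelevant direction), ``DM = D + I`` (direction-match) and
``OT = I`` (opposite-target, used as the estimate of the irrelevant
signal), linear summation of feature signals implies
``T - OT = (CM - OT) + (DM - OT)``.  The *additivity index*

    (T - OT) - [(CM - OT) + (DM - OT)]

is therefore exactly zero for any additive construction, positive for
super-additive conjunction coding, and invariant to adding a constant to
all four responses.

Color tuning is the least-squares slope of mean response against color
rank 1 (yellow) to 8 (red); direction tuning is the angle of the
rate-weighted vector sum over the eight directions (match stimuli
excluded from both).  Feature-based attention displaces tuning toward the
currently relevant feature; the per-neuron shift is quantified by the
sample-A minus sample-B slope difference (negative = toward the relevant
color) and the signed angular separation of preferred directions
(positive = toward the relevant direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    N_COLORS,
    N_DIRECTIONS,
    RELEVANT_DIRECTION_DEG,
    NeuronRecording,
    SampleID,
    aligned_counts,
    mean_rate,
    select_events,
)
from .selectivity import VDI_WINDOW

DIRECTION_EPS_FRACTION = 1e-6


@dataclass(frozen=True)
class ConditionResponses:
    """Normalized mean responses to the four stimulus classes.

    The latent color/direction/irrelevant components are not individually
    identifiable from these data; they enter only through the additivity
    index.  Normalization (division by the neuron's mean rate over all
    test windows) affects display, not the index's zero point.
    """

    T: float
    CM: float
    DM: float
    OT: float
    window: tuple[float, float]
    n_events: dict[str, int]


@dataclass(frozen=True)
class TuningResult:
    color_slope_A: float
    color_slope_B: float
    color_shift: float  # slope_A - slope_B; negative = toward the relevant color
    preferred_direction_A_deg: float | None
    preferred_direction_B_deg: float | None
    direction_shift_deg: float | None  # positive = toward the relevant direction


def condition_responses(
    neuron: NeuronRecording,
    window: tuple[float, float] = VDI_WINDOW,
    normalize: bool = True,
    min_events: int = 3,
    pref: SampleID | None = None,
) -> ConditionResponses:
    """Mean response per stimulus class in the RF, relative to the neuron's
    preferred identity.

    With preferred identity P (the sample conjunction evoking the larger
    response, e.g. test A for A-selective cells): T is the target (stimulus
    P in sample-P trials); CM and DM are the color- and direction-match
    stimuli of sample-P trials (relevant color or direction paired with an
    irrelevant partner feature); OT is the same physical stimulus P when it
    is behaviorally irrelevant, i.e. presented during other-sample trials.
    Responses are optionally normalized by the neuron's grand mean rate
    over all test-stimulus windows.
    """
    from .selectivity import preferred_identity_of

    if pref is None:
        pref = preferred_identity_of(neuron, window)
    other: SampleID = "B" if pref == "A" else "A"
    class_events = {
        "T": dict(samples=[pref], match_classes=["target"]),
        "CM": dict(samples=[pref], match_classes=["color_match"]),
        "DM": dict(samples=[pref], match_classes=["direction_match"]),
        "OT": dict(samples=[other], match_classes=["opposite_target"]),
    }
    dur = window[1] - window[0]
    rates = {}
    n_events = {}
    for key, sel in class_events.items():
        evs = select_events(neuron, locations=["IN"], **sel)
        if len(evs) < min_events:
            raise ValueError(f"class {key}: fewer than {min_events} events")
        rates[key] = mean_rate(aligned_counts(neuron, evs, window, check_bounds=False), dur)
        n_events[key] = len(evs)
    if normalize:
        all_evs = select_events(neuron, locations=["IN"])
        norm = mean_rate(aligned_counts(neuron, all_evs, window, check_bounds=False), dur)
        if norm > 0:
            rates = {k: v / norm for k, v in rates.items()}
    return ConditionResponses(
        T=rates["T"], CM=rates["CM"], DM=rates["DM"], OT=rates["OT"],
        window=window, n_events=n_events,
    )


def additivity_index(cr: ConditionResponses) -> float:
    """``(T - OT) - [(CM - OT) + (DM - OT)]``: zero for linear feature
    summation, positive for super-additive conjunction coding."""
    return (cr.T - cr.OT) - ((cr.CM - cr.OT) + (cr.DM - cr.OT))


def _mean_rates_by_feature(
    neuron: NeuronRecording,
    sample: SampleID,
    feature: str,
    window: tuple[float, float],
) -> np.ndarray:
    """Mean rate per color or direction level, match stimuli excluded."""
    n_levels = N_COLORS if feature == "color" else N_DIRECTIONS
    dur = window[1] - window[0]
    out = np.empty(n_levels)
    evs = select_events(
        neuron,
        locations=["IN"],
        samples=[sample],
        match_classes=["color_match", "direction_match", "other"],
    )
    if not evs:
        raise ValueError(f"no non-match events in sample {sample} trials")
    counts = aligned_counts(neuron, evs, window, check_bounds=False)
    levels = np.array(
        [
            ev.event.stimulus.color_index if feature == "color" else ev.event.stimulus.direction_index
            for ev in evs
        ]
    )
    for lvl in range(1, n_levels + 1):
        sel = levels == lvl
        if not sel.any():
            raise ValueError(f"missing {feature} level {lvl} in sample {sample} trials")
        out[lvl - 1] = mean_rate(counts[sel], dur)
    return out


def color_slope(
    neuron: NeuronRecording, sample: SampleID, window: tuple[float, float] = VDI_WINDOW
) -> float:
    """Least-squares slope of mean response against color rank (1-8)."""
    means = _mean_rates_by_feature(neuron, sample, "color", window)
    x = np.arange(1, N_COLORS + 1, dtype=float)
    return float(np.polyfit(x, means, 1)[0])


def color_shift(neuron: NeuronRecording, window: tuple[float, float] = VDI_WINDOW) -> float:
    """Sample-A minus sample-B color slope.  Yellow (rank 1) is relevant in
    sample A and red (rank 8) in sample B, so tuning attracted toward the
    relevant color lowers the A slope and raises the B slope: negative
    values mean shifts toward the relevant color."""
    return color_slope(neuron, "A", window) - color_slope(neuron, "B", window)


def preferred_direction(
    neuron: NeuronRecording, sample: SampleID, window: tuple[float, float] = VDI_WINDOW
) -> float | None:
    """Angle of the rate-weighted vector sum over the eight directions, or
    ``None`` when the resultant is negligible (flat tuning)."""
    means = _mean_rates_by_feature(neuron, sample, "direction", window)
    angles = np.deg2rad((np.arange(N_DIRECTIONS)) * (360.0 / N_DIRECTIONS))
    x = float(np.sum(means * np.cos(angles)))
    y = float(np.sum(means * np.sin(angles)))
    if np.hypot(x, y) < DIRECTION_EPS_FRACTION * np.sum(np.abs(means)):
        return None
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def _circ_dist_deg(a: float, b: float) -> float:
    """Unsigned circular distance in [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


def direction_shift(
    neuron: NeuronRecording, window: tuple[float, float] = VDI_WINDOW
) -> float | None:
    """Angular distance between preferred directions under sample A and B,
    signed positive when the sample-A preference sits closer to the
    relevant (sample A) direction than the sample-B preference does —
    i.e. positive = shift toward the relevant direction."""
    pa = preferred_direction(neuron, "A", window)
    pb = preferred_direction(neuron, "B", window)
    if pa is None or pb is None:
        return None
    magnitude = _circ_dist_deg(pa, pb)
    rel_a = RELEVANT_DIRECTION_DEG["A"]
    sign = 1.0 if _circ_dist_deg(pb, rel_a) >= _circ_dist_deg(pa, rel_a) else -1.0
    return sign * magnitude


def tuning_result(neuron: NeuronRecording, window: tuple[float, float] = VDI_WINDOW) -> TuningResult:
    """Bundle the color slopes, preferred directions and both attention
    shift measures for one neuron."""
    slope_a = color_slope(neuron, "A", window)
    slope_b = color_slope(neuron, "B", window)
    pa = preferred_direction(neuron, "A", window)
    pb = preferred_direction(neuron, "B", window)
    return TuningResult(
        color_slope_A=slope_a,
        color_slope_B=slope_b,
        color_shift=slope_a - slope_b,
        preferred_direction_A_deg=pa,
        preferred_direction_B_deg=pb,
        direction_shift_deg=direction_shift(neuron, window),
    )


def correlate_profiles(
    profiles: pd.DataFrame, x_field: str, y_field: str
) -> tuple[float, float]:
    """Pearson correlation with two-sided p between two per-neuron metrics,
    over neurons where both are present."""
    sub = profiles[[x_field, y_field]].dropna()
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 complete pairs for {x_field} vs {y_field}")
    x = sub[x_field].to_numpy(dtype=float)
    y = sub[y_field].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the fields")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def sliding_additivity(profiles: pd.DataFrame, width: int = 31) -> pd.DataFrame:
    """Moving average of the additivity index over VDI-ranked neurons
    (display companion to the per-neuron scatter)."""
    ranked = profiles.sort_values("vdi").reset_index(drop=True)
    roll = ranked["additivity_index"].rolling(width, center=True)
    return pd.DataFrame(
        {
            "vdi": ranked["vdi"],
            "additivity_sliding_mean": roll.mean(),
            "additivity_sliding_sd": roll.std(),
        }
    )
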