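"""Sliding-ROC selectivity, latency detection, and the visuo-decision index.

Two comparisons characterize each neuron around test-stimulus onset:
*identity* selectivity (responses to test stimulus A vs B, pooled over
match status) and *match* selectivity (responses to target vs
opposite-target stimuli, pooled over identity).  Each is a 200 ms window
sliding in 1 ms steps; the window's value is assigned to its center.  The
area under the ROC curve is the Mann-Whitney U statistic normalized by
``n1 * n2`` (ties count one half); significance is a two-sided Wilcoxon
rank-sum test, Bonferroni-corrected over the evaluated window centers.

A neuron's latency for a signal is the first time, between stimulus onset
and the session's mean reaction time, at which the sliding test is
significant for 100 consecutive milliseconds.  The visuo-decision index
(VDI) summarizes the balance of the two signals over 100-350 ms
post-onset: +1 is purely identity-selective, -1 purely match-selective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core import AlignedEvent, NeuronRecording, SAMPLE_STIMULI, aligned_counts, select_events, sliding_counts

Comparison = Literal["identity", "match", "match_in", "match_out"]

VDI_WINDOW = (100.0, 350.0)
DEFAULT_EPOCH = (-100.0, 450.0)
MIN_EVENTS_PER_SIDE = 5
LATENCY_RUN_MS = 100.0


@dataclass
class SelectivityTrace:
    times_ms: np.ndarray  # window centers
    roc: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray  # Bonferroni-corrected mask
    comparison: Comparison
    n_pref: int
    n_nonpref: int
    alpha: float
    step_ms: float
    latency_ms: float | None = None


@dataclass(frozen=True)
class VDIResult:
    vdi: float
    identity_strength: float
    match_strength: float
    window: tuple[float, float] = VDI_WINDOW


def roc_auc(counts_pref: np.ndarray, counts_nonpref: np.ndarray) -> float:
    """Probability that a random preferred-condition count exceeds a random
    non-preferred one, ties counted one half (Mann-Whitney U / (n1*n2))."""
    x = np.asarray(counts_pref, dtype=float)
    y = np.asarray(counts_nonpref, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def _roc_auc_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise AUC for count matrices of shape (n_events, n_times)."""
    n1, n2 = x.shape[0], y.shape[0]
    ranks = stats.rankdata(np.vstack([x, y]), axis=0)
    u = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)


def preferred_identity_of(
    neuron: NeuronRecording, window: tuple[float, float] = VDI_WINDOW
) -> str:
    """The sample conjunction (A or B) evoking the larger mean response in
    the given post-onset window, over test-stimulus presentations in the RF."""
    means = {}
    for side in ("A", "B"):
        evs = select_events(neuron, locations=["IN"], stimuli=[SAMPLE_STIMULI[side]])
        if not evs:
            raise ValueError(f"no test-{side} events in RF")
        means[side] = float(np.mean(aligned_counts(neuron, evs, window, check_bounds=False)))
    return "A" if means["A"] >= means["B"] else "B"


def _comparison_events(
    neuron: NeuronRecording, comparison: Comparison
) -> tuple[list[AlignedEvent], list[AlignedEvent]]:
    if comparison == "identity":
        pref = preferred_identity_of(neuron)
        nonpref = "B" if pref == "A" else "A"
        a = select_events(neuron, locations=["IN"], stimuli=[SAMPLE_STIMULI[pref]])
        b = select_events(neuron, locations=["IN"], stimuli=[SAMPLE_STIMULI[nonpref]])
    elif comparison in ("match", "match_in", "match_out"):
        loc = "OUT" if comparison == "match_out" else "IN"
        a = select_events(neuron, locations=[loc], match_classes=["target"])
        b = select_events(neuron, locations=[loc], match_classes=["opposite_target"])
    else:
        raise ValueError(f"unknown comparison: {comparison}")
    return a, b


def sliding_selectivity(
    neuron: NeuronRecording,
    comparison: Comparison,
    window_ms: float = 200.0,
    step_ms: float = 1.0,
    alpha: float = 0.01,
    epoch: tuple[float, float] = DEFAULT_EPOCH,
) -> SelectivityTrace:
    """Sliding-ROC trace for one comparison, aligned to test-stimulus onset.

    The analysis epoch spans ``epoch`` (default -100 to +450 ms) around
    onset; the Bonferroni family is the number of evaluated window centers.
    """
    pref_events, nonpref_events = _comparison_events(neuron, comparison)
    if len(pref_events) < MIN_EVENTS_PER_SIDE or len(nonpref_events) < MIN_EVENTS_PER_SIDE:
        raise ValueError(
            f"comparison {comparison}: needs >= {MIN_EVENTS_PER_SIDE} events per side "
            f"(got {len(pref_events)} vs {len(nonpref_events)})"
        )
    centers = np.arange(epoch[0], epoch[1] + 0.5 * step_ms, step_ms)
    x = sliding_counts(neuron, pref_events, centers, window_ms)
    y = sliding_counts(neuron, nonpref_events, centers, window_ms)
    res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic")
    roc = res.statistic / (x.shape[0] * y.shape[0])
    p = np.asarray(res.pvalue, dtype=float)
    significant = p < alpha / centers.size
    trace = SelectivityTrace(
        times_ms=centers,
        roc=np.asarray(roc, dtype=float),
        p_value=p,
        significant=significant,
        comparison=comparison,
        n_pref=x.shape[0],
        n_nonpref=y.shape[0],
        alpha=alpha,
        step_ms=step_ms,
    )
    trace.latency_ms = detect_latency(trace, neuron.session_mean_rt_ms)
    return trace


def detect_latency(trace: SelectivityTrace, session_mean_rt_ms: float) -> float | None:
    """Earliest time in [0, mean session RT] starting at least 100
    consecutive significant milliseconds; ``None`` if no such run."""
    mask = np.asarray(trace.significant, dtype=bool)
    times = trace.times_ms
    if not np.isfinite(session_mean_rt_ms):
        session_mean_rt_ms = float(times[-1])
    need = int(np.ceil(LATENCY_RUN_MS / trace.step_ms))
    # run-length encode the mask
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for start, stop in zip(idx[::2], idx[1::2]):
        # candidate start clipped to stimulus onset
        cand = start
        while cand < stop and times[cand] < 0:
            cand += 1
        if cand >= stop:
            continue
        t = float(times[cand])
        if t > session_mean_rt_ms:
            continue
        if stop - cand >= need:
            return t
    return None


def compute_vdi(
    identity_trace: SelectivityTrace,
    match_trace: SelectivityTrace,
    window: tuple[float, float] = VDI_WINDOW,
) -> VDIResult:
    """VDI = identity strength - match strength, each strength the mean of
    ``2 * |ROC - 0.5|`` over the window (default 100-350 ms post-onset)."""
    strengths = []
    for trace in (identity_trace, match_trace):
        sel = (trace.times_ms >= window[0]) & (trace.times_ms <= window[1])
        if not sel.any() or trace.times_ms[0] > window[0] or trace.times_ms[-1] < window[1]:
            raise ValueError(f"trace does not cover the window {window}")
        strengths.append(float(np.mean(2.0 * np.abs(trace.roc[sel] - 0.5))))
    return VDIResult(
        vdi=strengths[0] - strengths[1],
        identity_strength=strengths[0],
        match_strength=strengths[1],
        window=window,
    )


@dataclass(frozen=True)
class LatencyStats:
    mean_identity: float
    sd_identity: float
    n_identity: int
    mean_match: float
    sd_match: float
    n_match: int
    t_unpaired: float
    p_unpaired: float
    t_paired: float | None
    p_paired: float | None
    paired_no_difference: bool
    n_paired: int


def population_latency_stats(
    identity_latencies: Sequence[float],
    match_latencies: Sequence[float],
    paired: Sequence[tuple[float, float]] = (),
) -> LatencyStats:
    """Unpaired t-test of identity vs match latencies across neurons, plus a
    paired test on neurons selective for both signals.  All-zero paired
    differences yield an undefined t; that is reported as a
    ``paired_no_difference`` flag rather than a statistic."""
    ident = np.asarray(identity_latencies, dtype=float)
    match = np.asarray(match_latencies, dtype=float)
    if ident.size < 2 or match.size < 2:
        raise ValueError("need at least two latencies per group")
    t_un, p_un = stats.ttest_ind(ident, match)
    t_pd = p_pd = None
    no_diff = False
    pairs = np.asarray(paired, dtype=float)
    if pairs.size and pairs.shape[0] >= 2:
        diffs = pairs[:, 0] - pairs[:, 1]
        if np.allclose(diffs, 0.0):
            no_diff = True
        else:
            t_pd, p_pd = stats.ttest_rel(pairs[:, 0], pairs[:, 1])
            t_pd, p_pd = float(t_pd), float(p_pd)
    return LatencyStats(
        mean_identity=float(ident.mean()),
        sd_identity=float(ident.std(ddof=1)),
        n_identity=int(ident.size),
        mean_match=float(match.mean()),
        sd_match=float(match.std(ddof=1)),
        n_match=int(match.size),
        t_unpaired=float(t_un),
        p_unpaired=float(p_un),
        t_paired=t_pd,
        p_paired=p_pd,
        paired_no_difference=no_diff,
        n_paired=int(pairs.shape[0]) if pairs.size else 0,
    )
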