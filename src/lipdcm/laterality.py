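"""Spatial (IN vs OUT) comparison of match selectivity.

Match-selective activity could reflect a decision signal tied to the
stimulus in the neuron's receptive field, or a location-independent
process (motor preparation, reward expectancy).  After attention
equalization, match-vs-opposite-target ROC traces are computed separately
for targets inside and outside the RF; their difference is the laterality
index.  A bootstrap permutation test draws 1000 resampled ROC values per
location and compares all 10^6 cross pairs: the IN and OUT levels differ
significantly when more than 95% of (IN - OUT) differences share a sign
(strictly more; ties count as not positive).  The 10^6 pairwise
comparisons are evaluated as an exact cross-distribution tail fraction
without materializing the full product.

Classification treats bilateral selectivity as selectivity independent of
stimulus location: a neuron is *unilateral_in* (or *unilateral_out*) only
when the permutation test finds a significant IN-OUT difference over the
100-350 ms decision window *and* the weaker location shows no standalone
match selectivity (no 100 ms Bonferroni-significant run of its own).  A
neuron that is match-selective at both locations is *bilateral* even if
the two amplitudes differ — the cross-distribution test detects amplitude
asymmetry, not absence of selectivity, and its two one-sided 5% rules
would otherwise misclassify about 10% of truly location-independent
neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .core import NeuronRecording, aligned_counts, select_events
from .selectivity import VDI_WINDOW, SelectivityTrace, sliding_selectivity

Classification = Literal["bilateral", "unilateral_in", "unilateral_out"]

SIGNIFICANCE_FRACTION = 0.95


@dataclass
class LateralityResult:
    times_ms: np.ndarray
    roc_in: np.ndarray
    roc_out: np.ndarray
    laterality_index: np.ndarray  # roc_in - roc_out
    in_trace: SelectivityTrace | None = None
    out_trace: SelectivityTrace | None = None
    classification: Classification | None = None
    frac_in_gt_out: float | None = None  # tail fraction over the decision window
    n_boot: int = 1000


def laterality_trace(
    neuron: NeuronRecording,
    window_ms: float = 200.0,
    step_ms: float = 1.0,
) -> LateralityResult:
    """Sliding match-ROC traces for IN and OUT target locations and their
    difference.  The neuron should already be attention-equalized."""
    if neuron.task_variant != "two_location":
        raise ValueError("laterality analysis requires two-location data")
    tin = sliding_selectivity(neuron, "match_in", window_ms=window_ms, step_ms=step_ms)
    tout = sliding_selectivity(neuron, "match_out", window_ms=window_ms, step_ms=step_ms)
    return LateralityResult(
        times_ms=tin.times_ms,
        roc_in=tin.roc,
        roc_out=tout.roc,
        laterality_index=tin.roc - tout.roc,
        in_trace=tin,
        out_trace=tout,
    )


def bootstrap_rocs(
    counts_pref: np.ndarray,
    counts_nonpref: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ROC areas for ``n_boot`` with-replacement resamples of both groups."""
    x = np.asarray(counts_pref, dtype=float)
    y = np.asarray(counts_nonpref, dtype=float)
    bx = x[rng.integers(x.size, size=(n_boot, x.size))]
    by = y[rng.integers(y.size, size=(n_boot, y.size))]
    ranks = stats.rankdata(np.hstack([bx, by]), axis=1)
    u = ranks[:, : x.size].sum(axis=1) - x.size * (x.size + 1) / 2.0
    return u / (x.size * y.size)


def cross_fraction_greater(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of pairs (i, j) with ``a[i] > b[j]`` over the full cross
    product, ties excluded, computed via sorting in O((m+n) log n)."""
    b_sorted = np.sort(np.asarray(b, dtype=float))
    wins = np.searchsorted(b_sorted, np.asarray(a, dtype=float), side="left").sum()
    return float(wins) / (len(a) * len(b))


def cross_fraction_greater_naive(a: np.ndarray, b: np.ndarray) -> float:
    """Direct enumeration of all pairwise comparisons (reference oracle)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.mean(a[:, None] > b[None, :]))


def permutation_laterality_test(
    neuron: NeuronRecording,
    n_boot: int = 1000,
    seed: int = 0,
    window: tuple[float, float] = VDI_WINDOW,
    min_events: int = 5,
) -> LateralityResult:
    """Classify a neuron as bilaterally or unilaterally match-selective.

    Spike counts are aggregated over the decision window (default 100-350
    ms post-onset); ``n_boot`` bootstrap ROC values are drawn for each
    location and compared across the full ``n_boot ** 2`` product.
    """
    if neuron.task_variant != "two_location":
        raise ValueError("laterality analysis requires two-location data")
    rng = np.random.default_rng(seed)
    counts = {}
    for loc in ("IN", "OUT"):
        for mc in ("target", "opposite_target"):
            evs = select_events(neuron, locations=[loc], match_classes=[mc])
            if len(evs) < min_events:
                raise ValueError(f"fewer than {min_events} {mc} events at location {loc}")
            counts[(loc, mc)] = aligned_counts(neuron, evs, window, check_bounds=False)
    roc_in = bootstrap_rocs(counts[("IN", "target")], counts[("IN", "opposite_target")], n_boot, rng)
    roc_out = bootstrap_rocs(counts[("OUT", "target")], counts[("OUT", "opposite_target")], n_boot, rng)
    frac_in = cross_fraction_greater(roc_in, roc_out)
    frac_out = cross_fraction_greater(roc_out, roc_in)
    cls: Classification = "bilateral"
    if frac_in > SIGNIFICANCE_FRACTION:
        weaker = sliding_selectivity(neuron, "match_out")
        if weaker.latency_ms is None:
            cls = "unilateral_in"
    elif frac_out > SIGNIFICANCE_FRACTION:
        weaker = sliding_selectivity(neuron, "match_in")
        if weaker.latency_ms is None:
            cls = "unilateral_out"
    return LateralityResult(
        times_ms=np.array([np.mean(window)]),
        roc_in=np.array([roc_in.mean()]),
        roc_out=np.array([roc_out.mean()]),
        laterality_index=np.array([roc_in.mean() - roc_out.mean()]),
        in_trace=None,
        out_trace=None,
        classification=cls,
        frac_in_gt_out=frac_in,
        n_boot=n_boot,
    )
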