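"""End-to-end analysis: from a population dataset to per-neuron profiles.

The per-neuron profile table is the central artifact: for each neuron it
holds the visuo-decision index (VDI) with identity/match selectivity
strengths and latencies, the additivity index, color/direction tuning
shifts, the summary choice-probability correlation, and (for two-location
data) the laterality classification.  Population-level statistics —
latency ordering tests, the choice-probability-vs-VDI and
additivity-vs-VDI correlations — are computed from this table.

Selectivity analyses run on sample-equalized spike trains; the laterality
analysis runs on attention-equalized spike trains; tuning and choice
probability use the raw recording (choice probability is restricted to
preferred-sample trials, so sample-memory gain is constant there).
"""

from __future__ import annotations

import logging
import time
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import choice_probability
from .core import NeuronRecording, PopulationDataset
from .equalization import equalize_by_attention, equalize_by_sample
from .features import additivity_index, color_shift, condition_responses, direction_shift
from .laterality import permutation_laterality_test
from .selectivity import compute_vdi, population_latency_stats, sliding_selectivity

logger = logging.getLogger(__name__)


def equalize_dataset(dataset: PopulationDataset, seed: int = 0) -> PopulationDataset:
    """Sample-equalize every neuron once (the decimated spike trains are
    reused by all downstream analyses, including decoding).  Neurons whose
    ratio cannot be estimated are passed through unchanged."""
    root = np.random.default_rng(seed)
    out = []
    for neuron in dataset.neurons:
        try:
            eq, _ = equalize_by_sample(neuron, seed=int(root.integers(2**31 - 1)))
        except ValueError as err:
            logger.warning("neuron %s: equalization skipped (%s)", neuron.neuron_id, err)
            eq = neuron
        out.append(eq)
    return PopulationDataset(neurons=out, provenance=dict(dataset.provenance, sample_equalized=True))


def neuron_profile(
    neuron: NeuronRecording,
    seed: int = 0,
    step_ms: float = 1.0,
    with_laterality: bool = True,
    n_boot: int = 1000,
) -> dict:
    """All per-neuron derived scalars; analysis failures from insufficient
    data leave the corresponding fields missing (NaN) rather than aborting."""
    row: dict = {"neuron_id": neuron.neuron_id, "monkey_id": neuron.monkey_id}
    eq = neuron
    try:
        eq, plan = equalize_by_sample(neuron, seed=seed)
        row["sample_decimation_fraction"] = plan.removal_fraction
    except ValueError as err:
        logger.warning("neuron %s: sample equalization skipped (%s)", neuron.neuron_id, err)

    id_trace = match_trace = None
    try:
        id_trace = sliding_selectivity(eq, "identity", step_ms=step_ms)
        match_trace = sliding_selectivity(eq, "match", step_ms=step_ms)
        vdi = compute_vdi(id_trace, match_trace)
        row.update(
            vdi=vdi.vdi,
            identity_strength=vdi.identity_strength,
            match_strength=vdi.match_strength,
            identity_latency_ms=id_trace.latency_ms,
            match_latency_ms=match_trace.latency_ms,
            identity_selective=id_trace.latency_ms is not None,
            match_selective=match_trace.latency_ms is not None,
        )
    except ValueError as err:
        logger.warning("neuron %s: selectivity skipped (%s)", neuron.neuron_id, err)

    try:
        cr = condition_responses(eq)
        row["additivity_index"] = additivity_index(cr)
        row.update(resp_T=cr.T, resp_CM=cr.CM, resp_DM=cr.DM, resp_OT=cr.OT)
    except ValueError as err:
        logger.warning("neuron %s: condition responses skipped (%s)", neuron.neuron_id, err)

    try:
        row["color_shift"] = color_shift(neuron)
    except ValueError as err:
        logger.warning("neuron %s: color tuning skipped (%s)", neuron.neuron_id, err)
    try:
        row["direction_shift_deg"] = direction_shift(neuron)
    except ValueError as err:
        logger.warning("neuron %s: direction tuning skipped (%s)", neuron.neuron_id, err)

    try:
        cp = choice_probability(neuron)
        row["cp_summary_r"] = cp.summary_r
        row["cp_n_trials"] = cp.n_trials
    except ValueError as err:
        logger.warning("neuron %s: choice probability skipped (%s)", neuron.neuron_id, err)

    # the bilateral/unilateral distinction is only meaningful for neurons
    # that are match-selective in the first place
    if with_laterality and neuron.task_variant == "two_location" and row.get("match_selective"):
        try:
            eqa, _ = equalize_by_attention(neuron, seed=seed + 1)
            lat = permutation_laterality_test(eqa, n_boot=n_boot, seed=seed + 2)
            row["laterality_class"] = lat.classification
            row["laterality_frac_in_gt_out"] = lat.frac_in_gt_out
        except ValueError as err:
            logger.warning("neuron %s: laterality skipped (%s)", neuron.neuron_id, err)
    return row


def analyze_population(
    dataset: PopulationDataset,
    seed: int = 0,
    step_ms: float = 1.0,
    with_laterality: bool = True,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Per-neuron profile table for a whole dataset."""
    t0 = time.perf_counter()
    rows = []
    root = np.random.default_rng(seed)
    for neuron in dataset.neurons:
        rows.append(
            neuron_profile(
                neuron,
                seed=int(root.integers(2**31 - 1)),
                step_ms=step_ms,
                with_laterality=with_laterality,
                n_boot=n_boot,
            )
        )
    logger.info(
        "profiled %d neurons in %.1f s", len(rows), time.perf_counter() - t0
    )
    return pd.DataFrame(rows)


def latency_stats_from_profiles(profiles: pd.DataFrame):
    """Identity-vs-match latency comparison across the population."""
    ident = profiles["identity_latency_ms"].dropna()
    match = profiles["match_latency_ms"].dropna()
    both = profiles.dropna(subset=["identity_latency_ms", "match_latency_ms"])
    pairs = list(zip(both["identity_latency_ms"], both["match_latency_ms"]))
    return population_latency_stats(ident.to_numpy(), match.to_numpy(), pairs)
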