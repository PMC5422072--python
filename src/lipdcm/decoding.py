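"""Pseudo-population linear-SVM decoding with bootstrap significance.

Neurons recorded in separate sessions are combined into pseudo-trials by
independent per-neuron resampling: for each class, the stated sub-condition
composition is drawn with replacement per neuron (identity: 140 training
pseudo-trials per class as 70 target + 70 opposite-target presentations of
that stimulus, 60 test; match status: 70 target A + 70 target B vs the two
opposite-target pools; sample identity: 70 training / 30 test trials per
sample).  Training and testing draws come from disjoint source-event pools
so no source trial appears on both sides.

At each time point a linear maximum-margin classifier is trained on
standardized window spike counts (training statistics only) and scored on
the test pseudo-trials; the procedure repeats ``n_iter`` times and the
decoder counts as above chance (50%) at a time point when accuracy exceeds
chance in more than 99% of iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.svm import LinearSVC

from .core import NeuronRecording, PopulationDataset, SAMPLE_STIMULI, select_events

logger = logging.getLogger(__name__)

LabelScheme = Literal["identity", "match", "sample"]

#: sub-conditions (sample-conjunction stimulus side, match class) per class
_SCHEME_SUBCONDS: dict[str, dict[str, list[tuple[str, str]]]] = {
    "identity": {
        "A": [("A", "target"), ("A", "opposite_target")],
        "B": [("B", "target"), ("B", "opposite_target")],
    },
    "match": {
        "target": [("A", "target"), ("B", "target")],
        "nonmatch": [("A", "opposite_target"), ("B", "opposite_target")],
    },
}


@dataclass
class DecodeResult:
    times_ms: np.ndarray
    accuracy: np.ndarray  # mean over iterations
    iteration_accuracies: np.ndarray  # (n_iter, n_times)
    significant: np.ndarray
    label_scheme: LabelScheme
    n_neurons: int
    n_iter: int
    seed: int
    chance: float = 0.5
    significance_latency_ms: float | None = None


def _event_counts_matrix(
    neuron: NeuronRecording, rel_times: list[np.ndarray], centers: np.ndarray, window_ms: float
) -> np.ndarray:
    half = window_ms / 2.0
    lo_e, hi_e = centers - half, centers + half
    out = np.empty((len(rel_times), centers.size), dtype=np.float32)
    for i, rel in enumerate(rel_times):
        out[i] = np.searchsorted(rel, hi_e, side="left") - np.searchsorted(rel, lo_e, side="left")
    return out


def _neuron_pools(
    neuron: NeuronRecording,
    scheme: LabelScheme,
    centers: np.ndarray,
    window_ms: float,
) -> dict[tuple, np.ndarray] | None:
    """Counts matrices per sub-condition, or None if any pool is too small."""
    pools: dict[tuple, np.ndarray] = {}
    if scheme == "sample":
        for side in ("A", "B"):
            rels = []
            for i, trial in enumerate(neuron.trials):
                if trial.sample_identity != side or trial.attention != "IN":
                    continue
                if trial.outcome not in ("hit", "correct_reject"):
                    continue
                if not trial.test_events:
                    continue
                rels.append(neuron.spikes[i].spike_times_ms)  # trial-start aligned
            if len(rels) < 2:
                return None
            pools[(side,)] = _event_counts_matrix(neuron, rels, centers, window_ms)
        return pools
    for cls, subs in _SCHEME_SUBCONDS[scheme].items():
        for side, mc in subs:
            evs = select_events(
                neuron, locations=["IN"], stimuli=[SAMPLE_STIMULI[side]], match_classes=[mc]
            )
            if len(evs) < 2:
                return None
            rels = [
                neuron.spike_train(ev.trial.trial_id).spike_times_ms - ev.onset_ms for ev in evs
            ]
            pools[(side, mc)] = _event_counts_matrix(neuron, rels, centers, window_ms)
    return pools


def build_pseudotrials(
    pools_per_neuron: list[dict[tuple, np.ndarray]],
    classes: dict[str, list[tuple]],
    splits: list[dict[tuple, tuple[np.ndarray, np.ndarray]]],
    n_train_per_sub: int,
    n_test_per_sub: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble one iteration's train/test pseudo-trial tensors.

    Returns ``(X_train, y_train, X_test, y_test)`` with X of shape
    ``(n_pseudotrials, n_neurons, n_times)``.  Per neuron and
    sub-condition, training rows are drawn with replacement from that
    neuron's training pool and test rows from the disjoint test pool.
    """
    n_neurons = len(pools_per_neuron)
    n_times = next(iter(pools_per_neuron[0].values())).shape[1]
    class_names = list(classes)
    n_sub = {c: len(subs) for c, subs in classes.items()}
    n_train = {c: n_train_per_sub * n_sub[c] for c in class_names}
    n_test = {c: n_test_per_sub * n_sub[c] for c in class_names}
    X_train = np.empty((sum(n_train.values()), n_neurons, n_times), dtype=np.float32)
    X_test = np.empty((sum(n_test.values()), n_neurons, n_times), dtype=np.float32)
    y_train = np.concatenate([np.full(n_train[c], k) for k, c in enumerate(class_names)])
    y_test = np.concatenate([np.full(n_test[c], k) for k, c in enumerate(class_names)])
    for j, (pools, split) in enumerate(zip(pools_per_neuron, splits)):
        tr_row = te_row = 0
        for cls in class_names:
            for sub in classes[cls]:
                train_pool, test_pool = split[sub]
                tr_idx = train_pool[rng.integers(train_pool.size, size=n_train_per_sub)]
                te_idx = test_pool[rng.integers(test_pool.size, size=n_test_per_sub)]
                X_train[tr_row : tr_row + n_train_per_sub, j] = pools[sub][tr_idx]
                X_test[te_row : te_row + n_test_per_sub, j] = pools[sub][te_idx]
                tr_row += n_train_per_sub
                te_row += n_test_per_sub
    return X_train, y_train, X_test, y_test


def _make_splits(
    pools_per_neuron: list[dict[tuple, np.ndarray]],
    rng: np.random.Generator,
    train_frac: float = 0.7,
) -> list[dict[tuple, tuple[np.ndarray, np.ndarray]]]:
    """Partition each neuron's source events into disjoint train/test pools."""
    splits = []
    for pools in pools_per_neuron:
        split = {}
        for sub, mat in pools.items():
            n = mat.shape[0]
            perm = rng.permutation(n)
            k = max(1, min(n - 1, int(round(train_frac * n))))
            split[sub] = (perm[:k], perm[k:])
        splits.append(split)
    return splits


def decode_timecourse(
    dataset: PopulationDataset,
    label_scheme: LabelScheme,
    window_ms: float = 200.0,
    step_ms: float = 10.0,
    n_iter: int = 1000,
    seed: int = 0,
    t_range: tuple[float, float] | None = None,
    n_train_per_sub: int = 70,
    n_test_per_sub: int = 30,
    C: float = 1.0,
    permute_labels: bool = False,
) -> DecodeResult:
    """Time course of linear-SVM decoding accuracy for a label scheme.

    ``identity`` and ``match`` schemes align to test-stimulus onset
    (default epoch -100 to 450 ms); ``sample`` aligns to trial start and
    spans sample, delay and first test epochs.  ``permute_labels``
    shuffles class labels of the training and test pseudo-trials within
    each iteration, for null calibration.
    """
    if t_range is None:
        if label_scheme == "sample":
            epoch = 450.0 if dataset.neurons and dataset.neurons[0].task_variant == "two_location" else 550.0
            t_range = (window_ms / 2.0, 3 * epoch - window_ms / 2.0)
        else:
            t_range = (-100.0, 450.0)
    centers = np.arange(t_range[0], t_range[1] + 0.5 * step_ms, step_ms)

    if label_scheme == "sample":
        classes = {"A": [("A",)], "B": [("B",)]}
    else:
        classes = _SCHEME_SUBCONDS[label_scheme]

    pools_per_neuron = []
    kept = 0
    for neuron in dataset.neurons:
        pools = _neuron_pools(neuron, label_scheme, centers, window_ms)
        if pools is None:
            logger.warning("neuron %s lacks a sub-condition; excluded from decoding", neuron.neuron_id)
            continue
        pools_per_neuron.append(pools)
        kept += 1
    if kept == 0:
        raise ValueError("no neuron has all required sub-conditions")

    rng = np.random.default_rng(seed)
    accs = np.empty((n_iter, centers.size), dtype=float)
    clf = LinearSVC(C=C, dual="auto", max_iter=5000)
    for it in range(n_iter):
        splits = _make_splits(pools_per_neuron, rng)
        X_tr, y_tr, X_te, y_te = build_pseudotrials(
            pools_per_neuron, classes, splits, n_train_per_sub, n_test_per_sub, rng
        )
        if permute_labels:
            y_tr = rng.permutation(y_tr)
            y_te = rng.permutation(y_te)
        for c in range(centers.size):
            A = X_tr[:, :, c]
            B = X_te[:, :, c]
            mu = A.mean(axis=0)
            sd = A.std(axis=0)
            sd[sd == 0] = 1.0
            clf.fit((A - mu) / sd, y_tr)
            accs[it, c] = clf.score((B - mu) / sd, y_te)

    mean_acc = accs.mean(axis=0)
    above = (accs > 0.5).sum(axis=0)
    significant = above > 0.99 * n_iter
    latency = None
    post = np.flatnonzero(significant & (centers >= 0))
    if post.size:
        latency = float(centers[post[0]])
    return DecodeResult(
        times_ms=centers,
        accuracy=mean_acc,
        iteration_accuracies=accs,
        significant=significant,
        label_scheme=label_scheme,
        n_neurons=kept,
        n_iter=n_iter,
        seed=seed,
        significance_latency_ms=latency,
    )
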