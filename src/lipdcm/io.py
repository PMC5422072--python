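"""Readers and writers for population datasets.

Two storage dialects carry the same schema:

* ``tabular_bundle`` — a directory of four comma-separated files
  (``neurons.csv``, ``trials.csv``, ``events.csv``, ``spikes.csv``) plus a
  ``provenance.json`` sidecar.  Plain text, diffable, portable.
* ``structured_container`` — a single HDF5 file holding the same four
  tables as column datasets under ``/neurons``, ``/trials``, ``/events``
  and ``/spikes``, with provenance stored as a JSON root attribute.

Both dialects round-trip every field bit-exactly (floats are serialized
with shortest-round-trip representations).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd

from .core import (
    NeuronRecording,
    PopulationDataset,
    SchemaError,
    SpikeTrain,
    StimulusID,
    TestEvent,
    TrialRecord,
    validate_dataset,
)

Format = Literal["tabular_bundle", "structured_container"]

NEURON_COLS = ["neuron_id", "monkey_id", "task_variant", "session_mean_rt_ms"]
TRIAL_COLS = [
    "neuron_id", "trial_id", "sample_identity", "attention", "task_variant",
    "is_catch", "outcome", "rt_ms",
]
EVENT_COLS = [
    "neuron_id", "trial_id", "position_in_sequence", "is_distractor",
    "color_index", "direction_index", "location", "onset_ms", "duration_ms",
    "match_class",
]
SPIKE_COLS = ["neuron_id", "trial_id", "time_ms"]


def dataset_to_tables(dataset: PopulationDataset) -> dict[str, pd.DataFrame]:
    neurons, trials, events, spikes = [], [], [], []
    for n in dataset.neurons:
        neurons.append(
            dict(
                neuron_id=n.neuron_id,
                monkey_id=n.monkey_id,
                task_variant=n.task_variant,
                session_mean_rt_ms=n.session_mean_rt_ms,
            )
        )
        for t in n.trials:
            trials.append(
                dict(
                    neuron_id=n.neuron_id,
                    trial_id=t.trial_id,
                    sample_identity=t.sample_identity,
                    attention=t.attention,
                    task_variant=t.task_variant,
                    is_catch=t.is_catch,
                    outcome=t.outcome,
                    rt_ms=np.nan if t.rt_ms is None else t.rt_ms,
                )
            )
            for e in t.events:
                events.append(
                    dict(
                        neuron_id=n.neuron_id,
                        trial_id=t.trial_id,
                        position_in_sequence=e.position_in_sequence,
                        is_distractor=e.is_distractor,
                        color_index=e.stimulus.color_index,
                        direction_index=e.stimulus.direction_index,
                        location=e.location,
                        onset_ms=e.onset_ms,
                        duration_ms=e.duration_ms,
                        match_class=e.match_class,
                    )
                )
            times = n.spike_train(t.trial_id).spike_times_ms
            for s in times:
                spikes.append(dict(neuron_id=n.neuron_id, trial_id=t.trial_id, time_ms=s))
    return {
        "neurons": pd.DataFrame(neurons, columns=NEURON_COLS),
        "trials": pd.DataFrame(trials, columns=TRIAL_COLS),
        "events": pd.DataFrame(events, columns=EVENT_COLS),
        "spikes": pd.DataFrame(spikes, columns=SPIKE_COLS),
    }


def tables_to_dataset(
    tables: dict[str, pd.DataFrame],
    provenance: dict,
    strict: bool = True,
) -> PopulationDataset:
    for name, cols in [
        ("neurons", NEURON_COLS), ("trials", TRIAL_COLS),
        ("events", EVENT_COLS), ("spikes", SPIKE_COLS),
    ]:
        if name not in tables:
            raise SchemaError(f"missing table: {name}")
        missing = set(cols) - set(tables[name].columns)
        if missing:
            raise SchemaError(f"table {name} missing columns: {sorted(missing)}")

    trials_by_neuron = dict(iter(tables["trials"].groupby("neuron_id", sort=False)))
    events_by_key = dict(iter(tables["events"].groupby(["neuron_id", "trial_id"], sort=False)))
    spikes_by_key = dict(iter(tables["spikes"].groupby(["neuron_id", "trial_id"], sort=False)))

    neurons = []
    for nrow in tables["neurons"].itertuples(index=False):
        trows = trials_by_neuron.get(nrow.neuron_id)
        trials: list[TrialRecord] = []
        spike_trains: list[SpikeTrain] = []
        if trows is not None:
            for trow in trows.itertuples(index=False):
                key = (nrow.neuron_id, trow.trial_id)
                erows = events_by_key.get(key)
                evts = []
                if erows is not None:
                    for erow in erows.itertuples(index=False):
                        evts.append(
                            TestEvent(
                                stimulus=StimulusID(
                                    int(erow.color_index), int(erow.direction_index)
                                ),
                                location=str(erow.location),
                                onset_ms=float(erow.onset_ms),
                                duration_ms=float(erow.duration_ms),
                                match_class=str(erow.match_class),
                                position_in_sequence=int(erow.position_in_sequence),
                                is_distractor=bool(erow.is_distractor),
                            )
                        )
                evts.sort(key=lambda e: (e.onset_ms, e.is_distractor))
                rt = float(trow.rt_ms) if np.isfinite(trow.rt_ms) else None
                trials.append(
                    TrialRecord(
                        trial_id=int(trow.trial_id),
                        sample_identity=str(trow.sample_identity),
                        attention=str(trow.attention),
                        task_variant=str(trow.task_variant),
                        events=tuple(evts),
                        is_catch=bool(trow.is_catch),
                        outcome=str(trow.outcome),
                        rt_ms=rt,
                    )
                )
                srows = spikes_by_key.get(key)
                times = (
                    np.sort(srows["time_ms"].to_numpy(dtype=float))
                    if srows is not None
                    else np.empty(0)
                )
                spike_trains.append(SpikeTrain(trial_id=int(trow.trial_id), spike_times_ms=times))
        neurons.append(
            NeuronRecording(
                neuron_id=str(nrow.neuron_id),
                monkey_id=str(nrow.monkey_id),
                task_variant=str(nrow.task_variant),
                trials=trials,
                spikes=spike_trains,
                session_mean_rt_ms=float(nrow.session_mean_rt_ms),
            )
        )
    dataset = PopulationDataset(neurons=neurons, provenance=provenance)
    validate_dataset(dataset, strict=strict)
    return dataset


def write_dataset(dataset: PopulationDataset, path: str | os.PathLike, format: Format = "tabular_bundle") -> None:
    path = Path(path)
    tables = dataset_to_tables(dataset)
    if format == "tabular_bundle":
        path.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(path / f"{name}.csv", index=False)
        (path / "provenance.json").write_text(json.dumps(dataset.provenance, indent=1))
    elif format == "structured_container":
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.attrs["provenance"] = json.dumps(dataset.provenance)
            for name, df in tables.items():
                grp = f.create_group(name)
                for col in df.columns:
                    values = df[col].to_numpy()
                    if values.dtype == object or values.dtype.kind in "U":
                        values = values.astype(h5py.string_dtype())
                    grp.create_dataset(col, data=values)
    else:
        raise ValueError(f"unknown format: {format}")


def read_dataset(path: str | os.PathLike, format: Format = "tabular_bundle", strict: bool = True) -> PopulationDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular_bundle":
        tables = {}
        for name in ("neurons", "trials", "events", "spikes"):
            fp = path / f"{name}.csv"
            if not fp.exists():
                raise SchemaError(f"missing table file: {fp.name}")
            tables[name] = pd.read_csv(fp)
        prov_file = path / "provenance.json"
        provenance = json.loads(prov_file.read_text()) if prov_file.exists() else {}
    elif format == "structured_container":
        tables = {}
        with h5py.File(path, "r") as f:
            provenance = json.loads(f.attrs.get("provenance", "{}"))
            for name in ("neurons", "trials", "events", "spikes"):
                if name not in f:
                    raise SchemaError(f"missing table group: {name}")
                grp = f[name]
                cols = {}
                for col in grp:
                    values = grp[col][()]
                    if values.dtype.kind in ("S", "O"):
                        values = np.array([v.decode() for v in values])
                    cols[col] = values
                tables[name] = pd.DataFrame(cols)
    else:
        raise ValueError(f"unknown format: {format}")
    return tables_to_dataset(tables, provenance, strict=strict)
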