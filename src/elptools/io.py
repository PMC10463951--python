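"""Readers and writers for the pipeline's file formats.

* MEA recordings: HDF5 with ``/voltages`` (channels x samples) and
  ``sampling_rate`` / channel metadata attributes.
* Calcium traces: wide CSV — a ``time_s`` column plus one ratio column per
  neuron, preceded by two metadata rows (``animal_id``, ``group``) keyed in
  the ``time_s`` column.
* IntelliCage visits / schedule / corner assignments: plain CSVs with the
  schemas documented in :mod:`elptools.icage`.
* Lipid tables: samples x species CSV with a leading ``group`` column.
* Run manifests: JSON recording config, seed and outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .calcium import CalciumTrace
from .icage import TaskSchedule
from .mea import MEARecording

__all__ = [
    "save_mea_h5",
    "load_mea_h5",
    "write_calcium_csv",
    "read_calcium_csv",
    "write_visits_csv",
    "write_schedule_csv",
    "write_lipid_csv",
    "read_lipid_csv",
    "write_manifest",
]


def save_mea_h5(path, recording: MEARecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltages", data=recording.voltages.astype(np.float32))
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["duration"] = recording.duration
        f.attrs["slice_id"] = recording.slice_id
        f.attrs["group"] = recording.group
        f.attrs["channel_ids"] = [str(c) for c in recording.channel_ids]


def load_mea_h5(path) -> MEARecording:
    with h5py.File(path, "r") as f:
        return MEARecording(
            voltages=f["voltages"][...].astype(float),
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_ids=[str(c) for c in f.attrs.get("channel_ids", [])],
            slice_id=str(f.attrs.get("slice_id", "")),
            group=str(f.attrs.get("group", "")),
        )


def write_calcium_csv(path, traces: list[CalciumTrace]) -> None:
    """Wide trace CSV with animal/group metadata rows above the time grid."""
    if not traces:
        raise ValueError("no traces to write")
    times = traces[0].times
    cols = {"time_s": ["animal_id", "group"] + [f"{t:g}" for t in times]}
    for tr in traces:
        if tr.times.shape != times.shape or not np.allclose(tr.times, times):
            raise ValueError("all traces must share one time grid")
        cols[tr.neuron_id] = [tr.animal_id, tr.group] + [
            format(float(v), ".17g") for v in tr.ratios
        ]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_calcium_csv(path) -> list[CalciumTrace]:
    raw = pd.read_csv(path, dtype=str)
    meta = raw.iloc[:2].set_index("time_s")
    data = raw.iloc[2:]
    times = data["time_s"].astype(float).to_numpy()

    def _meta(row, col):
        v = meta.loc[row, col]
        return "" if pd.isna(v) else str(v)

    traces = []
    for col in raw.columns[1:]:
        traces.append(
            CalciumTrace(
                times=times,
                ratios=data[col].astype(float).to_numpy(),
                neuron_id=col,
                animal_id=_meta("animal_id", col),
                group=_meta("group", col),
            )
        )
    return traces


def write_visits_csv(path, visits: pd.DataFrame) -> None:
    visits.to_csv(path, index=False)


def write_schedule_csv(seg_path, assign_path, schedule: TaskSchedule) -> None:
    schedule.segments.to_csv(seg_path, index=False)
    pd.DataFrame(
        {
            "animal_id": list(schedule.ppl_corner),
            "ppl_corner": list(schedule.ppl_corner.values()),
        }
    ).to_csv(assign_path, index=False)


def write_lipid_csv(path, table: pd.DataFrame, groups: pd.Series) -> None:
    out = table.copy()
    out.insert(0, "group", groups.loc[table.index])
    out.to_csv(path, index_label="sample_id")


def read_lipid_csv(path) -> tuple[pd.DataFrame, pd.Series]:
    raw = pd.read_csv(path, index_col="sample_id")
    groups = raw.pop("group")
    return raw.astype(float), groups


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def write_manifest(path, config, seed: int, outputs: dict[str, str]) -> None:
    manifest = {
        "config": _jsonable(config),
        "seed": int(seed),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
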