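"""Plain-text serialization of the pipeline's objects.

Time series travel as tab-separated text (one row per region, first column
the region id); cohort tables as CSV; planted truth and iteration logs as
JSON; connectivity stacks as one delimited matrix per window plus a JSON
sidecar; assignment matrices as delimited network-name grids.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AssignmentMatrix,
    CanonicalPartition,
    ConnectivityStack,
    DynreconfError,
    TimeSeriesMatrix,
)
from .simulate import PlantedTruth, SwitchEvent


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ts.values, index=pd.Index(ts.region_ids, name="region"))
    header = f"# tr_seconds={ts.tr_seconds} subject={ts.subject_id} timepoint={ts.timepoint_id}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", header=False)
    return path


def read_timeseries(
    path: str | Path, tr_seconds: float | None = None
) -> TimeSeriesMatrix:
    path = Path(path)
    subject = timepoint = ""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        meta = dict(
            kv.split("=", 1) for kv in first.lstrip("#").split() if "=" in kv
        )
        tr_seconds = float(meta.get("tr_seconds", tr_seconds or "nan"))
        subject = meta.get("subject", "")
        timepoint = meta.get("timepoint", "")
        skip = 1
    else:
        skip = 0
    if tr_seconds is None or not np.isfinite(tr_seconds):
        raise DynreconfError(f"no repetition time for {path}")
    df = pd.read_csv(path, sep="\t", header=None, index_col=0, skiprows=skip)
    return TimeSeriesMatrix(
        values=df.to_numpy(float),
        tr_seconds=tr_seconds,
        region_ids=tuple(str(i) for i in df.index),
        subject_id=subject,
        timepoint_id=timepoint,
    )


def write_partition(partition: CanonicalPartition, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"region": list(partition.labels), "network": list(partition.labels.values())}
    ).to_csv(path, index=False)
    return path


def read_partition(
    path: str | Path, network_names: tuple[str, ...] | None = None
) -> CanonicalPartition:
    df = pd.read_csv(path)
    labels = dict(zip(df["region"].astype(str), df["network"].astype(str)))
    names = network_names or tuple(dict.fromkeys(labels.values()))
    return CanonicalPartition(labels=labels, network_names=names)


def write_stack(stack: ConnectivityStack, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k in range(stack.n_windows):
        np.savetxt(directory / f"window_{k:03d}.tsv", stack.matrices[k], delimiter="\t")
    sidecar = {
        "window_starts": stack.window_starts.tolist(),
        "window_length_volumes": int(stack.window_length_volumes),
        "weights_profile": np.asarray(stack.weights_profile).tolist(),
        "region_ids": list(stack.region_ids),
        "tr_seconds": stack.tr_seconds,
    }
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=1))
    return directory


def write_assignment(matrix: AssignmentMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        matrix.names, index=pd.Index(matrix.region_ids, name="region")
    ).to_csv(path, sep="\t", header=[f"w{k}" for k in range(matrix.n_windows)])
    log_path = path.with_suffix(".log.json")
    log_path.write_text(json.dumps(matrix.iteration_log, indent=1))
    return path


def write_truth(truth: PlantedTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "events": truth.to_records(),
        "group_of_subject": truth.group_of_subject,
        "planted_group_effect": truth.planted_group_effect,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_truth(path: str | Path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    events = [SwitchEvent(**{**e, "regions": tuple(e["regions"])}) for e in payload["events"]]
    return PlantedTruth(
        events=events,
        group_of_subject=payload["group_of_subject"],
        planted_group_effect=payload["planted_group_effect"],
    )


def dataclass_to_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(obj), indent=1, default=str))
    return path
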