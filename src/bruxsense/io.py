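"""Reading and writing the package's trace, event and report formats.

Traces travel as HDF5 (datasets ``values`` and ``sampling_rate``, plus
label/covariate tables) or as tidy CSV (``time_s, ch0..chN``) with a JSON
sidecar for labels and covariates.  Events are JSON lines; session reports
are single JSON documents written with sorted keys so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .acquire import CountTrace, OcclusionEvent
from .simulate import EpisodeLabel, SensorTrace

__all__ = [
    "write_trace_h5", "read_trace_h5", "write_trace_csv", "read_trace_csv",
    "read_trace", "write_events_jsonl", "read_events_jsonl",
    "write_counts_csv", "write_report_json",
]


def _labels_to_records(trace: SensorTrace) -> list[dict]:
    return [dataclasses.asdict(lab) | {"peak_per_channel": list(lab.peak_per_channel)}
            for lab in trace.labels]


def _records_to_labels(records: list[dict]) -> list[EpisodeLabel]:
    return [EpisodeLabel(start=int(r["start"]), end=int(r["end"]),
                         peak_per_channel=tuple(r.get("peak_per_channel", ())),
                         kind=r.get("kind", "clench"))
            for r in records]


def write_trace_h5(trace: SensorTrace, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=trace.values)
        f.create_dataset("sampling_rate", data=trace.sampling_rate)
        f.attrs["labels"] = json.dumps(_labels_to_records(trace))
        f.attrs["covariates"] = json.dumps(trace.covariates)


def read_trace_h5(path: str | Path) -> SensorTrace:
    with h5py.File(path, "r") as f:
        return SensorTrace(
            values=f["values"][...],
            sampling_rate=float(f["sampling_rate"][()]),
            labels=_records_to_labels(json.loads(f.attrs.get("labels", "[]"))),
            covariates=json.loads(f.attrs.get("covariates", "[]")),
        )


def write_trace_csv(trace: SensorTrace, path: str | Path,
                    sidecar: bool = True) -> None:
    path = Path(path)
    t = np.arange(trace.n_samples) / trace.sampling_rate
    cols = {"time_s": t}
    for c in range(trace.n_channels):
        cols[f"ch{c}"] = trace.values[c]
    pd.DataFrame(cols).to_csv(path, index=False)
    if sidecar and (trace.labels or trace.covariates):
        meta = {"sampling_rate": trace.sampling_rate,
                "labels": _labels_to_records(trace),
                "covariates": trace.covariates}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_trace_csv(path: str | Path) -> SensorTrace:
    path = Path(path)
    df = pd.read_csv(path)
    channels = [c for c in df.columns if c.startswith("ch")]
    values = df[channels].to_numpy().T
    if len(df) > 1:
        fs = 1.0 / float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
    else:
        fs = 1.0
    labels: list[EpisodeLabel] = []
    covariates: list[dict] = []
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta.get("sampling_rate", fs))
        labels = _records_to_labels(meta.get("labels", []))
        covariates = meta.get("covariates", [])
    return SensorTrace(values=values, sampling_rate=fs,
                       labels=labels, covariates=covariates)


def read_trace(path: str | Path) -> SensorTrace:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return read_trace_h5(path)
    if path.suffix == ".csv":
        return read_trace_csv(path)
    raise ValueError(f"unsupported trace format {path.suffix!r}")


def write_counts_csv(counts: CountTrace, path: str | Path) -> None:
    cols = {f"ch{c}": counts.counts[c] for c in range(counts.n_channels)}
    pd.DataFrame(cols).to_csv(path, index=False)


def write_events_jsonl(events: list[OcclusionEvent], sampling_rate: float,
                       path: str | Path) -> None:
    with open(path, "w") as f:
        for e in events:
            rec = {"start_s": e.start / sampling_rate,
                   "end_s": e.end / sampling_rate,
                   "duration_s": e.duration,
                   "peaks": list(e.peak_per_channel),
                   "mean_force": e.mean_force}
            f.write(json.dumps(rec, sort_keys=True) + "\n")


def read_events_jsonl(path: str | Path) -> list[dict]:
    return [json.loads(line) for line in Path(path).read_text().splitlines()
            if line.strip()]


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=1))
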