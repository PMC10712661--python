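"""Delimited text I/O for traces, markers and recordings.

Traces are tab-separated files with ``# key=value`` header lines (rate,
units, t0, channels) followed by one column per channel. Recordings are
directories of such files plus the protocol marker file and a JSON
ground-truth sidecar. Values round-trip exactly (written with repr
precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import protocol as proto
from .dsp import SignalTrace
from .synthetic import MultimodalRecording

TRACE_FILES = {
    "gsr": "gsr.tsv", "ecg": "ecg.tsv", "bvp": "bvp.tsv",
    "eeg": "eeg.tsv", "pupil_left": "pupil_left.tsv",
    "pupil_right": "pupil_right.tsv",
}


def write_trace(trace: SignalTrace, path) -> None:
    path = Path(path)
    labels = trace.channel_labels or [f"ch{i}" for i in range(trace.n_channels)]
    with open(path, "w") as fh:
        fh.write(f"# rate={trace.rate!r}\n")
        fh.write(f"# units={trace.units}\n")
        fh.write(f"# t0={trace.t0!r}\n")
        fh.write("# channels=" + ",".join(labels) + "\n")
        data = np.atleast_2d(trace.data)
        np.savetxt(fh, data.T, delimiter="\t", fmt="%.17g")


def read_trace(path) -> SignalTrace:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
    data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2).T
    labels = [l for l in meta.get("channels", "").split(",") if l]
    if data.shape[0] == 1:
        data = data[0]
        labels = labels[:1] if len(labels) == 1 else []
    return SignalTrace(data, rate=float(meta["rate"]), units=meta.get("units", ""),
                       channel_labels=labels if isinstance(data, np.ndarray)
                       and data.ndim == 2 else [],
                       t0=float(meta.get("t0", 0.0)))


def schedule_from_markers(markers: pd.DataFrame) -> proto.ProtocolSchedule:
    """Rebuild a ProtocolSchedule from the tidy marker table."""
    sessions = markers[markers["kind"].isin(proto.KINDS)]
    stimuli = markers[markers["kind"] == "stimulus"]
    phase_order = list(dict.fromkeys(sessions["phase"]))
    blocks: list[list[proto.SessionWindow]] = []
    for phase in phase_order:
        block = []
        for _, row in sessions[sessions["phase"] == phase].iterrows():
            t0, t1 = row["onset_s"], row["onset_s"] + row["duration_s"]
            evs = stimuli[(stimuli["phase"] == phase) & (stimuli["onset_s"] >= t0)
                          & (stimuli["onset_s"] < t1)]
            events = [proto.StimulusEvent(
                modality=e["modality"], valence_class=e["valence_class"],
                arousal_level=int(e["arousal_level"]), onset=float(e["onset_s"]),
                duration=float(e["duration_s"])) for _, e in evs.iterrows()]
            block.append(proto.SessionWindow(
                phase=phase, kind=row["kind"],
                arousal_level=int(row["arousal_level"]),
                t_start=float(t0), t_end=float(t1), events=events))
        block.sort(key=lambda w: w.t_start)
        blocks.append(block)
    return proto.ProtocolSchedule(phases=blocks, phase_order=phase_order,
                                  phase_order_seed=-1)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dict__"):
        return {"__type__": type(obj).__name__, **_jsonable(vars(obj))}
    return obj


def write_recording(rec: MultimodalRecording, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in TRACE_FILES.items():
        trace = getattr(rec, attr)
        if trace is not None:
            write_trace(trace, outdir / fname)
    proto.write_markers(rec.schedule, outdir / "markers.tsv")
    if rec.rr_true is not None:
        np.savetxt(outdir / "rr_true.tsv", rec.rr_true.r_times, fmt="%.17g")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(_jsonable(rec.truth), fh, indent=1)


def load_recording(path) -> MultimodalRecording:
    path = Path(path)
    markers = proto.read_markers(path / "markers.tsv")
    rec = MultimodalRecording(schedule=schedule_from_markers(markers))
    for attr, fname in TRACE_FILES.items():
        f = path / fname
        if f.exists():
            setattr(rec, attr, read_trace(f))
    rr_file = path / "rr_true.tsv"
    if rr_file.exists():
        from .hrv import RRSeries
        rec.rr_true = RRSeries(np.atleast_1d(np.loadtxt(rr_file)))
    truth_file = path / "truth.json"
    if truth_file.exists():
        with open(truth_file) as fh:
            rec.truth = json.load(fh)
    return rec


def write_rpeaks(rr, rate: float, path) -> None:
    """Two-column annotation file (sample_index, time_s)."""
    idx = np.round(rr.r_times * rate).astype(int)
    np.savetxt(path, np.column_stack([idx, rr.r_times]),
               fmt=["%d", "%.17g"], delimiter="\t",
               header="sample_index\ttime_s")


def read_rpeaks(path):
    from .hrv import RRSeries
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    return RRSeries(arr[:, 1])
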