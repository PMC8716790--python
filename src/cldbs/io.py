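"""CSV readers/writers with JSON provenance sidecars.

Every trace is a plain CSV on a shared seconds-from-start clock, written at
full float precision so a write/read round trip is bit-lossless.  A sidecar
``<name>.json`` carries units, the sampling/update rate, the seed and a
config hash; a missing sidecar is tolerated with a warning so hand-made
files still load.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import StateTrace
from .sensing import FeatureStream, SenseConfig
from .stimulation import ClosedLoopTrace
from .synthetic import LFPRecording, SymptomTrace

__all__ = [
    "write_symptom_trace", "read_symptom_trace",
    "write_recording", "read_recording",
    "write_feature_stream", "read_feature_stream",
    "write_state_trace", "read_state_trace",
    "write_closed_loop_trace", "read_closed_loop_trace",
]

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write(path: str | Path, frame: pd.DataFrame, meta: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if "time" in frame.columns and len(frame) > 1:
        if np.any(np.diff(frame["time"].to_numpy()) <= 0):
            raise ValueError(f"{path}: time column must be strictly increasing")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        warnings.warn(f"missing sidecar {sidecar}; units/provenance unknown")
        meta = {}
    return frame, meta


def write_symptom_trace(path: str | Path, trace: SymptomTrace, **meta) -> None:
    frame = pd.DataFrame(
        {"time": trace.times, "score": trace.score, "state": trace.state}
    )
    _write(path, frame, {
        "kind": "symptom_trace", "units": {"time": "s", "score": "0-10 NRS"},
        "cutoff": trace.cutoff, **meta,
    })


def read_symptom_trace(path: str | Path) -> SymptomTrace:
    frame, meta = _read(path)
    cutoff = float(meta.get("cutoff", 5.0))
    return SymptomTrace(
        frame["time"].to_numpy(float),
        frame["score"].to_numpy(float),
        frame["state"].to_numpy(int),
        cutoff,
    )


def write_recording(path: str | Path, rec: LFPRecording, **meta) -> None:
    frame = pd.DataFrame({"time": rec.times})
    for i, ch in enumerate(rec.channels):
        frame[ch] = rec.samples[i]
    _write(path, frame, {
        "kind": "lfp_recording", "units": {"time": "s", "channels": "uV"},
        "fs": rec.fs, "events": rec.events, **meta,
    })


def read_recording(path: str | Path) -> LFPRecording:
    frame, meta = _read(path)
    channels = [c for c in frame.columns if c != "time"]
    t = frame["time"].to_numpy(float)
    fs = float(meta.get("fs", 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0))
    events = [(float(a), str(b)) for a, b in meta.get("events", [])]
    return LFPRecording(fs, channels, frame[channels].to_numpy(float).T, events)


def write_feature_stream(path: str | Path, stream: FeatureStream, **meta) -> None:
    frame = pd.DataFrame({"time": stream.times})
    for j, name in enumerate(stream.names):
        frame[name.replace(":", "_")] = stream.values[:, j]
    _write(path, frame, {
        "kind": "feature_stream", "units": {"time": "s", "features": "uV^2"},
        "names": stream.names, "normalized": stream.normalized,
        "sense_config": stream.config.model_dump(mode="json"),
        "channel_index": stream.channel_index, **meta,
    })


def read_feature_stream(path: str | Path) -> FeatureStream:
    frame, meta = _read(path)
    names = meta.get("names") or [c for c in frame.columns if c != "time"]
    cfg = SenseConfig.model_validate(meta["sense_config"]) if "sense_config" in meta \
        else SenseConfig()
    cols = [c for c in frame.columns if c != "time"]
    return FeatureStream(
        frame["time"].to_numpy(float),
        frame[cols].to_numpy(float),
        list(names),
        cfg,
        {k: int(v) for k, v in meta.get("channel_index", {}).items()},
        normalized=bool(meta.get("normalized", False)),
    )


def write_state_trace(path: str | Path, trace: StateTrace, **meta) -> None:
    frame = pd.DataFrame({"time": trace.times, "state": trace.state})
    _write(path, frame, {
        "kind": "state_trace", "units": {"time": "s"},
        "update_interval": trace.update_interval, "changes": trace.changes, **meta,
    })


def read_state_trace(path: str | Path) -> StateTrace:
    frame, meta = _read(path)
    changes = [
        (float(t), int(a), int(b), str(c)) for t, a, b, c in meta.get("changes", [])
    ]
    return StateTrace(
        frame["time"].to_numpy(float),
        frame["state"].to_numpy(int),
        changes,
        meta.get("update_interval"),
    )


def write_closed_loop_trace(path: str | Path, cl: ClosedLoopTrace, **meta) -> None:
    _write(path, cl.to_frame(), {
        "kind": "closed_loop_trace",
        "units": {"time": "s", "amp": "mA", "score": "0-10 NRS"},
        "update_interval": cl.update_interval, "changes": cl.changes, **meta,
    })


def read_closed_loop_trace(path: str | Path) -> ClosedLoopTrace:
    frame, meta = _read(path)
    changes = [
        (float(t), int(a), int(b), str(c)) for t, a, b, c in meta.get("changes") or []
    ]
    return ClosedLoopTrace(
        times=frame["time"].to_numpy(float),
        ld=frame["ld"].to_numpy(float),
        state=frame["state"].to_numpy(int),
        amp_cmd=frame["amp_cmd"].to_numpy(float),
        amp_eff=frame["amp_eff"].to_numpy(float),
        score=frame["score"].to_numpy(float),
        update_interval=float(meta.get("update_interval", 0.5)),
        changes=changes,
    )
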