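"""File formats: event TSVs, raw traces with JSON sidecars, BrainVision EEG.

Event tables are two-column TSVs (``time_ms``, ``label``), times integer
milliseconds on the laboratory clock (t = 0 at recording start).
Continuous single-channel traces are stored as raw float32 with a JSON
sidecar carrying the sampling rate.  EEG is written in the BrainVision
triplet (.vhdr/.vmrk text headers + .eeg float32 multiplexed binary),
readable by any EEG toolbox including :mod:`mne`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, EpochArray, EventSet


# ---------------------------------------------------------------------------
# event tables


def write_events(path, events: EventSet) -> None:
    rows = []
    for label, times in events.times_ms.items():
        for t in times:
            rows.append((int(round(t)), label))
    rows.sort()
    df = pd.DataFrame(rows, columns=["time_ms", "label"])
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> EventSet:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, np.ndarray] = {}
    for label, grp in df.groupby("label"):
        out[str(label)] = grp["time_ms"].to_numpy(dtype=float)
    return EventSet(out)


def write_times(path, times_ms, label: str) -> None:
    write_events(path, EventSet({label: np.asarray(times_ms)}))


# ---------------------------------------------------------------------------
# raw traces


def write_trace(path, trace: np.ndarray, srate: float, name: str = "trace") -> None:
    path = Path(path)
    np.asarray(trace, dtype="<f4").tofile(path)
    sidecar = {"name": name, "srate_hz": srate, "n_samples": int(len(trace)),
               "dtype": "float32-le"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    trace = np.fromfile(path, dtype="<f4").astype(float)
    if len(trace) != meta["n_samples"]:
        raise ValueError(f"{path}: expected {meta['n_samples']} samples")
    return trace, float(meta["srate_hz"])


# ---------------------------------------------------------------------------
# BrainVision


def write_brainvision(basepath, rec: EEGRecording) -> Path:
    """Write ``basepath``.vhdr/.vmrk/.eeg (multiplexed IEEE float32, uV)."""
    base = Path(basepath)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    interval_us = int(round(1e6 / rec.srate))
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.ch_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n[Common Infos]\n"
        f"DataFile={stem}.eeg\n\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )
    rec.data.T.astype("<f4").tofile(eeg)
    pos = {"ch_pos": {n: list(map(float, p)) for n, p in zip(rec.ch_names, rec.ch_pos)}}
    base.with_suffix(".pos.json").write_text(json.dumps(pos))
    return vhdr


def read_brainvision(vhdr_path) -> EEGRecording:
    """Read a BrainVision triplet back through mne."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    posfile = Path(vhdr_path).with_suffix(".pos.json")
    if posfile.exists():
        pos = json.loads(posfile.read_text())["ch_pos"]
        ch_pos = np.array([pos[n] for n in raw.ch_names])
    else:
        ch_pos = np.zeros((len(raw.ch_names), 3))
    return EEGRecording(raw.get_data() * 1e6, raw.info["sfreq"],
                        list(raw.ch_names), ch_pos)


# ---------------------------------------------------------------------------
# epochs and ground truth


def write_epochs(basepath, ep: EpochArray) -> None:
    base = Path(basepath)
    np.save(base.with_suffix(".npy"), ep.data)
    meta = {
        "times_ms": ep.times_ms.tolist(),
        "ch_names": ep.ch_names,
        "baseline_ms": list(ep.baseline_ms),
        "condition": ep.condition,
        "events_ms": None if ep.events_ms is None else ep.events_ms.tolist(),
        "ch_pos": None if ep.ch_pos is None else ep.ch_pos.tolist(),
    }
    base.with_suffix(".json").write_text(json.dumps(meta))


def read_epochs(basepath) -> EpochArray:
    base = Path(basepath)
    data = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return EpochArray(
        data,
        np.asarray(meta["times_ms"]),
        meta["ch_names"],
        tuple(meta["baseline_ms"]),
        meta["condition"],
        None if meta["events_ms"] is None else np.asarray(meta["events_ms"]),
        None if meta["ch_pos"] is None else np.asarray(meta["ch_pos"]),
    )
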