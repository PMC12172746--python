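"""Core in-memory containers shared across the pipeline.

Times are milliseconds on the laboratory clock with t = 0 at recording
start, unless a container says otherwise.  Voltages are microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EVENT_LABELS = ("touch", "goal", "non_goal", "ignored", "tactile")


@dataclass
class EventSet:
    """Labeled event times on a common clock.

    times_ms : per-label arrays of event times (ms, sorted).
    provenance : free-form record of how each label stream was obtained.
    """

    times_ms: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in list(self.times_ms.items()):
            arr = np.asarray(v, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"event times for {k!r} must be 1-D")
            if np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            self.times_ms[k] = arr

    def get(self, label: str) -> np.ndarray:
        return self.times_ms.get(label, np.empty(0))

    def with_label(self, label: str, times, provenance: str = "") -> "EventSet":
        out = EventSet(dict(self.times_ms), dict(self.provenance))
        out.times_ms[label] = np.sort(np.asarray(times, dtype=float))
        if provenance:
            out.provenance[label] = provenance
        return out


@dataclass
class EEGRecording:
    """Continuous multichannel EEG: ``data`` is (n_channels, n_samples) in uV."""

    data: np.ndarray
    srate: float
    ch_names: list[str]
    ch_pos: np.ndarray  # (n_channels, 3) metres
    bads: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel count mismatch between data and ch_names")
        self.ch_pos = np.asarray(self.ch_pos, dtype=float)
        if len({tuple(p) for p in np.round(self.ch_pos, 9)}) != len(self.ch_names):
            raise ValueError("channel positions must be unique")
        unknown = set(self.bads) - set(self.ch_names)
        if unknown:
            raise ValueError(f"bad channels not in montage: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.data.copy(), self.srate, list(self.ch_names),
            self.ch_pos.copy(), list(self.bads),
        )

    def to_mne(self):
        """Convert to an :class:`mne.io.RawArray` (volts) with a dig montage."""
        import mne

        info = mne.create_info(self.ch_names, self.srate, ch_types="eeg")
        raw = mne.io.RawArray(self.data * 1e-6, info, verbose="error")
        montage = mne.channels.make_dig_montage(
            ch_pos={n: p for n, p in zip(self.ch_names, self.ch_pos)},
            coord_frame="head",
        )
        raw.set_montage(montage, verbose="error")
        raw.info["bads"] = list(self.bads)
        return raw


@dataclass
class EpochArray:
    """Event-locked trials: ``data`` is (n_trials, n_channels, n_times) in uV.

    ``times_ms`` is the within-epoch time axis relative to the event;
    ``baseline_ms`` the (start, end) window whose per-trial, per-channel
    mean has been (or will be) subtracted; ``events_ms`` maps each trial
    to its source event time on the recording clock.
    """

    data: np.ndarray
    times_ms: np.ndarray
    ch_names: list[str]
    baseline_ms: tuple[float, float]
    condition: str = ""
    events_ms: np.ndarray | None = None
    ch_pos: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis length mismatch")
        lo, hi = self.baseline_ms
        if lo < self.times_ms[0] - 1e-9 or hi > self.times_ms[-1] + 1e-9:
            raise ValueError("baseline window must lie within the epoch")
        if self.events_ms is not None:
            self.events_ms = np.asarray(self.events_ms, dtype=float)
            if self.events_ms.size != self.data.shape[0]:
                raise ValueError("one source event per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def average(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def copy(self) -> "EpochArray":
        return EpochArray(
            self.data.copy(), self.times_ms.copy(), list(self.ch_names),
            tuple(self.baseline_ms), self.condition,
            None if self.events_ms is None else self.events_ms.copy(),
            None if self.ch_pos is None else self.ch_pos.copy(),
        )
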