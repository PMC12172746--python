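"""EEG conditioning, epoching, artifact rejection, tactile selection.

The conditioning chain mirrors standard event-related practice: bad
(high-impedance) channels are replaced by spherical-spline interpolation
from their neighbors, the continuous signal is zero-phase band-passed
(0.5-30 Hz for ERPs, 0.5-45 Hz for spectral analysis, 1-45 Hz for the
tactile probe), trials are cut in a -2..+2 s window with the -2..-1.5 s
pre-movement baseline, trials crossing +-80 uV are rejected, and only
participants retaining more than 50 trials per movement class enter the
group statistics.  Tactile-stimulation epochs are split by whether the
stimulation coincides (within +-500 ms) with a goal or a non-goal
movement landmark; stimulations near both classes are dropped.

Blink removal is a no-op hook here: a caller may plug any cleaner with
the ``EEGRecording -> EEGRecording`` signature into the pipeline.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import EEGRecording, EpochArray

logger = logging.getLogger(__name__)

BAND_PRESETS = {
    "erp": (0.5, 30.0),
    "spectral": (0.5, 45.0),
    "tactile": (1.0, 45.0),
}

DEFAULT_WINDOW_MS = (-2000.0, 2000.0)
DEFAULT_BASELINE_MS = (-2000.0, -1500.0)
TACTILE_WINDOW_MS = (-100.0, 400.0)
TACTILE_BASELINE_MS = (-100.0, -25.0)
ARTIFACT_LIMIT_UV = 80.0
MIN_TRIALS = 50
COINCIDENCE_MS = 500.0


def drop_and_interpolate(rec: EEGRecording, impedances_kohm: dict,
                         limit_kohm: float = 10.0,
                         max_bad_fraction: float = 0.25,
                         neighbor_radius_factor: float = 2.0) -> EEGRecording:
    """Replace channels above the impedance limit by spherical splines.

    Channels whose impedance exceeds ``limit_kohm`` are marked bad and
    re-estimated from the remaining channels (spherical-spline
    interpolation via mne).  Refuses to interpolate more than a quarter
    of the montage, or a channel with no neighbor within
    ``neighbor_radius_factor`` times the median nearest-neighbor
    distance.
    """
    missing = set(rec.ch_names) - set(impedances_kohm)
    if missing:
        raise ValueError(f"impedance entries missing for {sorted(missing)}")
    bads = [ch for ch in rec.ch_names if impedances_kohm[ch] > limit_kohm]
    if not bads:
        return rec.copy()
    if len(bads) > max_bad_fraction * rec.n_channels:
        raise ValueError(
            f"{len(bads)} of {rec.n_channels} channels exceed {limit_kohm} kOhm; "
            "interpolation would be unreliable"
        )
    d = np.linalg.norm(rec.ch_pos[:, None] - rec.ch_pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    radius = neighbor_radius_factor * np.median(d.min(axis=1))
    good = [i for i, ch in enumerate(rec.ch_names) if ch not in bads]
    for ch in bads:
        i = rec.ch_names.index(ch)
        if d[i, good].min() > radius:
            raise ValueError(f"channel {ch} has no neighbor within {radius:.3f} m")
    out = rec.copy()
    out.bads = bads
    raw = out.to_mne()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw.interpolate_bads(reset_bads=True, verbose="error")
    out.data = raw.get_data() * 1e6
    out.bads = []
    return out


def bandpass_eeg(rec: EEGRecording, band="erp", order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass; ``band`` is a preset name or
    a (lo, hi) pair in Hz."""
    lo, hi = BAND_PRESETS[band] if isinstance(band, str) else band
    if not (0 < lo < hi < rec.srate / 2):
        raise ValueError(f"invalid band ({lo}, {hi}) at srate {rec.srate}")
    sos = butter(order, (lo, hi), btype="bandpass", fs=rec.srate, output="sos")
    out = rec.copy()
    out.data = sosfiltfilt(sos, out.data, axis=1)
    return out


def baseline_correct(data: np.ndarray, times_ms: np.ndarray,
                     baseline_ms) -> np.ndarray:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    mask = (times_ms >= baseline_ms[0]) & (times_ms <= baseline_ms[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    return data - data[..., mask].mean(axis=-1, keepdims=True)


def epoch(rec: EEGRecording, events_ms: np.ndarray,
          window_ms=DEFAULT_WINDOW_MS, baseline_ms=DEFAULT_BASELINE_MS,
          condition: str = "", band=None) -> EpochArray:
    """Cut baseline-corrected trials around each event.

    Events closer than the window extent to a recording edge are dropped
    with a log entry.  If ``band`` is given the recording is band-passed
    first (preset name or (lo, hi)).
    """
    if band is not None:
        rec = bandpass_eeg(rec, band)
    k0 = int(round(window_ms[0] * rec.srate / 1000.0))
    k1 = int(round(window_ms[1] * rec.srate / 1000.0))
    times = np.arange(k0, k1 + 1) / rec.srate * 1000.0
    kept, trials = [], []
    for t in np.asarray(events_ms, dtype=float):
        c = int(round(t * rec.srate / 1000.0))
        if c + k0 < 0 or c + k1 >= rec.n_samples:
            logger.info("event at %.0f ms too close to recording edge; dropped", t)
            continue
        kept.append(t)
        trials.append(rec.data[:, c + k0 : c + k1 + 1])
    if not trials:
        raise ValueError("no events far enough from the recording edges")
    data = baseline_correct(np.stack(trials), times, baseline_ms)
    return EpochArray(data, times, list(rec.ch_names), tuple(baseline_ms),
                      condition, np.asarray(kept), rec.ch_pos.copy())


def reject_artifacts(ep: EpochArray, limit_uv: float = ARTIFACT_LIMIT_UV
                     ) -> EpochArray:
    """Drop trials with any sample beyond +-``limit_uv`` (post-baseline)."""
    bad = np.any(np.abs(ep.data) > limit_uv, axis=(1, 2))
    if bad.all():
        raise ValueError(f"all trials cross +-{limit_uv} uV; nothing survives")
    out = ep.copy()
    out.data = ep.data[~bad]
    if ep.events_ms is not None:
        out.events_ms = ep.events_ms[~bad]
    return out


def enforce_min_trials(*epoch_arrays: EpochArray,
                       minimum: int = MIN_TRIALS) -> bool:
    """Include a participant iff every condition keeps > ``minimum`` trials."""
    return all(ep.n_trials > minimum for ep in epoch_arrays)


def assign_tactile(tactile_ms: np.ndarray, goal_ms: np.ndarray,
                   nongoal_ms: np.ndarray,
                   coincidence_ms: float = COINCIDENCE_MS):
    """Split stimulations by the movement class they coincide with.

    A stimulation belongs to a class when a landmark of that class lies
    within the +-500 ms coincidence window; stimulations near both
    classes (ambiguous) or near neither are dropped.
    """
    def near(t, events):
        events = np.asarray(events, dtype=float)
        if events.size == 0:
            return False
        return bool(np.abs(events - t).min() <= coincidence_ms)

    goal_hits, nongoal_hits = [], []
    for t in np.asarray(tactile_ms, dtype=float):
        g, n = near(t, goal_ms), near(t, nongoal_ms)
        if g and not n:
            goal_hits.append(t)
        elif n and not g:
            nongoal_hits.append(t)
    return np.asarray(goal_hits), np.asarray(nongoal_hits)


def tactile_epochs(rec: EEGRecording, tactile_ms: np.ndarray,
                   goal_ms: np.ndarray, nongoal_ms: np.ndarray,
                   window_ms=TACTILE_WINDOW_MS,
                   baseline_ms=TACTILE_BASELINE_MS,
                   coincidence_ms: float = COINCIDENCE_MS
                   ) -> tuple[EpochArray | None, EpochArray | None]:
    """Tactile-stimulation epochs split by coinciding movement class.

    Band preset ``tactile`` (1-45 Hz), -100..+400 ms window, baseline
    -100..-25 ms.  Returns ``(goal_coinciding, nongoal_coinciding)``;
    an empty class yields ``None`` with a warning.
    """
    filtered = bandpass_eeg(rec, "tactile")
    g_times, n_times = assign_tactile(tactile_ms, goal_ms, nongoal_ms,
                                      coincidence_ms)
    out = []
    for times, name in ((g_times, "tactile_goal"), (n_times, "tactile_non_goal")):
        if times.size == 0:
            warnings.warn(f"no tactile stimulations for condition {name}")
            out.append(None)
            continue
        out.append(epoch(filtered, times, window_ms, baseline_ms, name))
    return tuple(out)
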