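"""Synthetic recording sessions with full ground truth.

A session emulates roughly an hour-scale smartphone-usage recording at
desk scale: a touchscreen log on a shifted device clock, 1 kHz thumb
flexion and force traces, solenoid tactile-stimulation triggers, and
multichannel EEG carrying class-specific event-locked components on top
of 1/f background noise and an ongoing beta-band oscillation.

Goal-directed events are thumb movements that produce a logged touch;
non-goal-directed events are kinematically similar movements placed more
than a second away from every touch, so that a downstream detector can
recover them as isolated false positives.  All generator defaults encode
the study conditions the pipeline is designed for; every stream is
reproducible bit-for-bit from ``SessionConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import EEGRecording
from .montage import Montage

EPOCH_RANGE_MS = (-2000.0, 2000.0)


class PackingError(ValueError):
    """Requested event counts do not fit the session duration."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class EffectTemplate:
    """One event-locked EEG component.

    Additive components (``band is None``) add ``amplitude_uv`` times a
    unit envelope to the listed channels inside ``window_ms``.  Carrier
    components modulate the power envelope of the ongoing band-limited
    oscillation by ``depth`` (fractional amplitude change, peak of the
    Hann envelope; -1 silences the carrier, +1 doubles it).
    """

    name: str
    channels: tuple[str, ...]
    window_ms: tuple[float, float]
    amplitude_uv: float = 0.0
    shape: str = "hann"  # "hann" or "ramp_up"
    band: tuple[float, float] | None = None
    depth: float = 0.0

    def __post_init__(self):
        t0, t1 = self.window_ms
        if not (EPOCH_RANGE_MS[0] <= t0 < t1 <= EPOCH_RANGE_MS[1]):
            raise ValueError(
                f"template {self.name!r}: window {self.window_ms} outside the "
                f"{EPOCH_RANGE_MS} ms epoch range"
            )
        if not -1.0 <= self.depth <= 1.0:
            raise ValueError("modulation depth must be in [-1, 1]")
        if self.shape not in ("hann", "ramp_up"):
            raise ValueError(f"unknown template shape {self.shape!r}")

    def envelope(self, times_ms: np.ndarray) -> np.ndarray:
        """Unit-amplitude envelope sampled at ``times_ms`` (0 outside window)."""
        t0, t1 = self.window_ms
        u = (np.asarray(times_ms, dtype=float) - t0) / (t1 - t0)
        inside = (u >= 0) & (u <= 1)
        out = np.zeros(u.shape)
        if self.shape == "hann":
            out[inside] = np.sin(np.pi * u[inside]) ** 2
        else:  # ramp_up: rises from 0 to 1 across the window
            out[inside] = np.sin(0.5 * np.pi * u[inside]) ** 2
        return out

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        """Additive voltage time course in uV (zero for carrier templates)."""
        if self.band is not None:
            return np.zeros(np.asarray(times_ms).shape)
        return self.amplitude_uv * self.envelope(times_ms)


@dataclass(frozen=True)
class MovementParams:
    """Thumb-flexion bump family and sensor noise."""

    bump_width_s: float = 0.4       # time base; support is 2x this, < 2 s
    amplitude: float = 1.0
    width_jitter: float = 0.15      # fractional SD of per-event width
    amp_jitter: float = 0.2         # fractional SD of per-event amplitude
    noise_rms: float = 0.05
    force_pulse_width_s: float = 0.05
    force_noise_rms: float = 0.02
    refractory_s: float = 0.5       # minimum inter-goal gap


@dataclass(frozen=True)
class EEGParams:
    n_channels: int = 64
    eeg_srate: float | None = None   # defaults to the session srate
    noise_exponent: float = 1.0      # 1/f^chi background
    noise_rms_uv: float = 10.0
    beta_band: tuple[float, float] = (16.0, 24.0)
    beta_rms_uv: float = 4.0
    amp_scale: float = 1.0           # subject-level scaling of additive templates
    nongoal_attenuation: float = 0.3
    goal_templates: tuple[EffectTemplate, ...] | None = None
    nongoal_templates: tuple[EffectTemplate, ...] | None = None
    tactile_templates: tuple[EffectTemplate, ...] | None = None


@dataclass(frozen=True)
class SessionConfig:
    """Study conditions for one synthetic session."""

    duration_s: float = 1200.0
    srate: float = 1000.0
    n_goal: int = 300
    n_nongoal: int = 100
    nongoal_after_bias: float = 0.7
    clock_offset_ms: float = 350.0
    clock_drift_ppm: float = 0.0
    movement: MovementParams = field(default_factory=MovementParams)
    eeg: EEGParams = field(default_factory=EEGParams)
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.srate <= 0:
            raise ValueError("duration and srate must be positive")
        if self.n_goal < 0 or self.n_nongoal < 0:
            raise ValueError("event counts must be non-negative")
        if not 0.0 <= self.nongoal_after_bias <= 1.0:
            raise ValueError("nongoal_after_bias must be in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Oracle record of everything injected into a session."""

    true_touch_times_lab: np.ndarray
    true_nongoal_times_lab: np.ndarray
    clock_offset_ms: float
    clock_drift_ppm: float
    tactile_times_ms: np.ndarray
    templates: dict[str, tuple[EffectTemplate, ...]] = field(default_factory=dict)

    def validate(self, duration_s: float) -> None:
        hi = duration_s * 1000.0
        for arr in (self.true_touch_times_lab, self.true_nongoal_times_lab,
                    self.tactile_times_ms):
            a = np.asarray(arr)
            if a.size and (a.min() < 0 or a.max() > hi):
                raise ValueError("ground-truth times outside the session")


@dataclass
class Session:
    config: SessionConfig
    movement: np.ndarray
    force: np.ndarray
    touch_log_device_ms: np.ndarray
    tactile_times_ms: np.ndarray
    truth: SyntheticGroundTruth
    eeg: EEGRecording | None = None
    montage: Montage | None = None


# ---------------------------------------------------------------------------
# default effect templates


def default_goal_templates(montage: Montage) -> tuple[EffectTemplate, ...]:
    """Event-locked components surrounding a goal-directed touch."""
    lsm = tuple(montage.groups["left_sensorimotor"])
    occ = tuple(montage.groups["occipital"])
    fc = tuple(montage.groups["fronto_central"])
    beta_ch = lsm + fc
    return (
        EffectTemplate("premovement_positivity", lsm, (-700.0, 0.0), 2.0, "ramp_up"),
        EffectTemplate("motor_negativity", lsm, (-300.0, 200.0), -4.0),
        EffectTemplate("visual_negativity", occ, (200.0, 450.0), -3.0),
        EffectTemplate("consolidation_positivity", fc, (500.0, 700.0), 3.0),
        EffectTemplate("beta_suppression", beta_ch, (-1200.0, 500.0),
                       band=(12.0, 30.0), depth=-0.5),
        EffectTemplate("beta_rebound", beta_ch, (400.0, 700.0),
                       band=(12.0, 30.0), depth=0.4),
    )


def default_nongoal_templates(
    montage: Montage, attenuation: float = 0.3
) -> tuple[EffectTemplate, ...]:
    """Dampened components surrounding a non-goal-directed movement."""
    lsm = tuple(montage.groups["left_sensorimotor"])
    fc = tuple(montage.groups["fronto_central"])
    return (
        EffectTemplate("premovement_positivity", lsm, (-700.0, 0.0), 2.0, "ramp_up"),
        EffectTemplate("motor_negativity", lsm, (-300.0, 200.0), -4.0 * attenuation),
        EffectTemplate("error_negativity", fc, (200.0, 280.0), -2.0),
        EffectTemplate("beta_suppression", lsm, (-350.0, 450.0),
                       band=(12.0, 30.0), depth=-0.35),
    )


def default_tactile_templates(montage: Montage) -> tuple[EffectTemplate, ...]:
    """Early somatosensory deflection; identical in both coincidence classes."""
    lsm = tuple(montage.groups["left_sensorimotor"])
    return (EffectTemplate("somatosensory_response", lsm, (25.0, 120.0), 3.0),)


# ---------------------------------------------------------------------------
# event streams


def _goal_isis(n: int, rng: np.random.Generator, refractory_s: float) -> np.ndarray:
    """Inter-touch intervals: log-normal mode ~1 s with a 18% pause component."""
    pause = rng.random(n) < 0.18
    short = rng.lognormal(mean=math.log(1.0) + 0.45**2, sigma=0.45, size=n)
    long = rng.lognormal(mean=math.log(7.0) + 0.5**2, sigma=0.5, size=n)
    isi = np.where(pause, long, short)
    return np.maximum(isi, refractory_s)


def make_events(
    config: SessionConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw goal and non-goal event times (ms, lab clock) for a session.

    Goal events form a renewal stream whose inter-event intervals have a
    log-normal mode near 1 s plus occasional longer pauses.  Non-goal
    events are placed inside inter-goal gaps at least 1.05 s away from
    every goal (so they remain isolated under the downstream +-1 s
    matching rule), preferentially just after the preceding goal with
    probability ``nongoal_after_bias``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    margin_s = 2.5  # keep epochs clear of the recording edges
    lo, hi = margin_s, config.duration_s - margin_s
    if hi <= lo:
        raise PackingError("duration too short for the 2.5 s edge margins")

    if config.n_goal == 0:
        goal_s = np.empty(0)
    else:
        isis = _goal_isis(config.n_goal, rng, config.movement.refractory_s)
        goal_s = lo + np.cumsum(isis)
        if goal_s[-1] > hi:
            raise PackingError(
                f"n_goal={config.n_goal} does not fit duration_s="
                f"{config.duration_s}: events span {goal_s[-1]:.1f} s"
            )

    nongoal_s = _place_nongoal(goal_s, config, rng, lo, hi)
    return np.round(goal_s * 1000.0), np.round(np.sort(nongoal_s) * 1000.0)


_NG_MARGIN_S = 1.2   # minimum distance from any goal event
_NG_SPACING_S = 1.0  # slot spacing inside a gap


def _place_nongoal(goal_s, config, rng, lo, hi):
    n = config.n_nongoal
    if n == 0:
        return np.empty(0)
    if goal_s.size == 0:
        # no goals to anchor to: plain renewal stream, bimodal intervals
        isis = np.where(
            rng.random(n) < 0.65,
            rng.lognormal(math.log(1.0) + 0.36, 0.6, n),
            rng.lognormal(math.log(10.0) + 0.1225, 0.35, n),
        )
        t = lo + np.cumsum(isis)
        if t[-1] > hi:
            raise PackingError(
                f"n_nongoal={n} does not fit duration_s={config.duration_s}"
            )
        return t

    # slots inside inter-goal gaps, split into an after-goal pool (nearest
    # goal precedes) and a before-goal pool (nearest goal follows)
    bounds = np.concatenate([[lo - _NG_MARGIN_S], goal_s, [hi + _NG_MARGIN_S]])
    after_pool: list[float] = []
    before_pool: list[float] = []
    for i in range(len(bounds) - 1):
        g0, g1 = bounds[i], bounds[i + 1]
        start, end = g0 + _NG_MARGIN_S, g1 - _NG_MARGIN_S
        if end < start:
            continue
        mid = 0.5 * (g0 + g1)
        head = i == 0                 # no preceding goal
        tail = i == len(bounds) - 2   # no following goal
        for j in range(3):
            p = start + j * _NG_SPACING_S
            if p > end:
                break
            if not head and (tail or p < mid - 0.05):
                after_pool.append(p)
        for j in range(3):
            p = end - j * _NG_SPACING_S
            if p < start:
                break
            if not tail and (head or p > mid + 0.05):
                before_pool.append(p)
    if len(after_pool) + len(before_pool) < n:
        raise PackingError(
            f"n_nongoal={n} exceeds the {len(after_pool) + len(before_pool)} "
            f"placement slots left by n_goal={config.n_goal} within "
            f"duration_s={config.duration_s}"
        )
    rng.shuffle(after_pool)
    rng.shuffle(before_pool)
    times = []
    for _ in range(n):
        take_after = rng.random() < config.nongoal_after_bias
        pool = after_pool if take_after else before_pool
        if not pool:
            pool = before_pool if take_after else after_pool
        times.append(pool.pop() + rng.uniform(-0.1, 0.1))
    return np.asarray(times)


def make_tactile_triggers(
    duration_s: float, rng: np.random.Generator | None = None, seed: int = 0
) -> np.ndarray:
    """Solenoid trigger times (ms): i.i.d. Uniform(0.75, 1.0) s intervals."""
    if duration_s <= 1.0:
        raise ValueError("duration must exceed 1 s")
    if rng is None:
        rng = np.random.default_rng(seed)
    times = []
    t = rng.uniform(0.75, 1.0)
    while t < duration_s:
        times.append(t)
        t += rng.uniform(0.75, 1.0)
    return np.round(np.asarray(times) * 1000.0)


def shift_to_device_clock(
    times_lab_ms: np.ndarray, offset_ms: float, drift_ppm: float = 0.0
) -> np.ndarray:
    """Map lab-clock times to the device clock: t_dev = t + offset + drift*t."""
    if not np.isfinite(offset_ms):
        raise ValueError("offset must be finite")
    if abs(drift_ppm) >= 1000:
        raise ValueError("|drift| must be below 1000 ppm")
    t = np.asarray(times_lab_ms, dtype=float)
    return t + offset_ms + drift_ppm * 1e-6 * t


def shift_to_lab_clock(
    times_device_ms: np.ndarray, offset_ms: float, drift_ppm: float = 0.0
) -> np.ndarray:
    """Exact inverse of :func:`shift_to_device_clock`."""
    t = np.asarray(times_device_ms, dtype=float)
    return (t - offset_ms) / (1.0 + drift_ppm * 1e-6)


# ---------------------------------------------------------------------------
# kinematic traces


def _flexion_bump(width_s: float, srate: float) -> tuple[np.ndarray, int]:
    """Gaussian-windowed asymmetric raised cosine; apex exactly at index `apex`."""
    rise = 0.6 * width_s
    decay = 1.4 * width_s
    n_r = int(round(rise * srate))
    n_d = int(round(decay * srate))
    t = (np.arange(n_r + n_d + 1) - n_r) / srate
    y = np.empty(t.shape)
    pre = t <= 0
    y[pre] = 0.5 * (1.0 - np.cos(np.pi * (t[pre] + rise) / rise))
    y[~pre] = 0.5 * (1.0 + np.cos(np.pi * t[~pre] / decay))
    y *= np.exp(-(t**2) / (2.0 * (0.7 * width_s) ** 2))
    return y, n_r


def make_movement_trace(
    goal_ms: np.ndarray,
    nongoal_ms: np.ndarray,
    config: SessionConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize the flexion-sensor and force-sensor traces.

    Both movement classes draw bumps from the same shape family (width
    and amplitude jittered per event) so their median event-locked
    profiles are nearly identical; only goal events add a force pulse,
    co-timed with the bump apex.
    """
    mp = config.movement
    if mp.amplitude < 0:
        raise ValueError("movement amplitude must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = int(round(config.duration_s * config.srate))
    movement = np.zeros(n)
    force = np.zeros(n)

    def add_bumps(times_ms, with_force):
        for t_ms in np.sort(np.concatenate([times_ms])):
            width = mp.bump_width_s * (1.0 + mp.width_jitter * rng.standard_normal())
            width = float(np.clip(width, 0.3 * mp.bump_width_s, 2.0 * mp.bump_width_s))
            amp = mp.amplitude * (1.0 + mp.amp_jitter * rng.standard_normal())
            amp = float(np.clip(amp, 0.1 * mp.amplitude, None))
            bump, apex = _flexion_bump(width, config.srate)
            c = int(round(t_ms / 1000.0 * config.srate))
            a, b = c - apex, c - apex + bump.size
            s0, s1 = max(a, 0), min(b, n)
            movement[s0:s1] += amp * bump[s0 - a : s1 - a]
            if with_force:
                pw = int(round(mp.force_pulse_width_s * config.srate))
                tt = np.arange(-pw, pw + 1) / config.srate
                pulse = np.cos(0.5 * np.pi * tt / mp.force_pulse_width_s) ** 2
                fa, fb = c - pw, c + pw + 1
                f0, f1 = max(fa, 0), min(fb, n)
                force[f0:f1] += amp * pulse[f0 - fa : f1 - fa]

    add_bumps(np.asarray(goal_ms, dtype=float), with_force=True)
    add_bumps(np.asarray(nongoal_ms, dtype=float), with_force=False)
    if mp.noise_rms > 0:
        movement += mp.noise_rms * rng.standard_normal(n)
    if mp.force_noise_rms > 0:
        force += mp.force_noise_rms * rng.standard_normal(n)
    return movement, force


# ---------------------------------------------------------------------------
# EEG synthesis


def _one_over_f_noise(shape, exponent, rng):
    """Rows of 1/f^exponent noise, unit variance per row."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    scale = np.zeros(f.shape)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, shape[-1], axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-12)


def _narrowband_noise(shape, band, srate, rng):
    """Rows of band-limited noise, unit variance per row."""
    white = rng.standard_normal(shape)
    sos = butter(4, band, btype="bandpass", fs=srate, output="sos")
    x = sosfiltfilt(sos, white, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-12)


def make_eeg(
    goal_ms: np.ndarray,
    nongoal_ms: np.ndarray,
    tactile_ms: np.ndarray,
    config: SessionConfig,
    montage: Montage | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EEGRecording, SyntheticGroundTruth]:
    """Continuous EEG with class-specific event-locked components.

    Background is 1/f noise plus an ongoing beta-band oscillation whose
    power envelope is modulated by the carrier templates (suppression /
    rebound); additive templates inject the slow ERP components.
    """
    ep = config.eeg
    if montage is None:
        montage = Montage(ep.n_channels)
    if montage.n_channels < 16:
        raise ValueError("montage must have at least 16 channels")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    srate = ep.eeg_srate or config.srate
    n = int(round(config.duration_s * srate))

    goal_t = ep.goal_templates
    if goal_t is None:
        goal_t = default_goal_templates(montage)
    ng_t = ep.nongoal_templates
    if ng_t is None:
        ng_t = default_nongoal_templates(montage, ep.nongoal_attenuation)
    tac_t = ep.tactile_templates
    if tac_t is None:
        tac_t = default_tactile_templates(montage)

    by_class = {"goal": (goal_ms, goal_t), "non_goal": (nongoal_ms, ng_t),
                "tactile": (tactile_ms, tac_t)}

    # per-channel additive waveforms and carrier envelopes
    data = np.zeros((montage.n_channels, n))
    env = {}  # channel index -> beta power envelope (amplitude domain)
    for times_ms, templates in by_class.values():
        idx = np.round(np.asarray(times_ms, dtype=float) / 1000.0 * srate).astype(int)
        for tpl in templates:
            t0, t1 = tpl.window_ms
            k0 = int(math.floor(t0 / 1000.0 * srate))
            k1 = int(math.ceil(t1 / 1000.0 * srate))
            seg_t = np.arange(k0, k1 + 1) / srate * 1000.0
            chans = [montage.index(c) for c in tpl.channels]
            if tpl.band is None:
                seg = ep.amp_scale * tpl.waveform(seg_t)
            else:
                seg = tpl.depth * tpl.envelope(seg_t)
            for c in chans:
                if tpl.band is not None and c not in env:
                    env[c] = np.ones(n)
                for e in idx:
                    a, b = e + k0, e + k0 + seg.size
                    s0, s1 = max(a, 0), min(b, n)
                    if s0 >= s1:
                        continue
                    if tpl.band is None:
                        data[c, s0:s1] += seg[s0 - a : s1 - a]
                    else:
                        env[c][s0:s1] += seg[s0 - a : s1 - a]

    # background: 1/f noise plus (modulated) ongoing beta oscillation,
    # synthesized for all channels at once
    C = montage.n_channels
    if ep.noise_rms_uv > 0:
        data += ep.noise_rms_uv * _one_over_f_noise((C, n), ep.noise_exponent,
                                                    rng)
    if ep.beta_rms_uv > 0:
        beta = ep.beta_rms_uv * _narrowband_noise((C, n), ep.beta_band, srate,
                                                  rng)
        for c, e in env.items():
            beta[c] *= np.clip(e, 0.02, None)
        data += beta

    rec = EEGRecording(data, srate, list(montage.names), montage.positions.copy())
    truth = SyntheticGroundTruth(
        true_touch_times_lab=np.asarray(goal_ms, dtype=float),
        true_nongoal_times_lab=np.asarray(nongoal_ms, dtype=float),
        clock_offset_ms=config.clock_offset_ms,
        clock_drift_ppm=config.clock_drift_ppm,
        tactile_times_ms=np.asarray(tactile_ms, dtype=float),
        templates={"goal": goal_t, "non_goal": ng_t, "tactile": tac_t},
    )
    truth.validate(config.duration_s)
    return rec, truth


# ---------------------------------------------------------------------------
# whole sessions


def simulate_session(config: SessionConfig, with_eeg: bool = True) -> Session:
    """Generate a complete synthetic session (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    goal_ms, nongoal_ms = make_events(config, rng)
    movement, force = make_movement_trace(goal_ms, nongoal_ms, config, rng)
    tactile_ms = make_tactile_triggers(config.duration_s, rng)
    montage = Montage(config.eeg.n_channels)
    eeg = truth = None
    if with_eeg:
        eeg, truth = make_eeg(goal_ms, nongoal_ms, tactile_ms, config, montage, rng)
    if truth is None:
        truth = SyntheticGroundTruth(
            np.asarray(goal_ms, dtype=float), np.asarray(nongoal_ms, dtype=float),
            config.clock_offset_ms, config.clock_drift_ppm,
            np.asarray(tactile_ms, dtype=float),
        )
        truth.validate(config.duration_s)
    touch_device = shift_to_device_clock(
        goal_ms, config.clock_offset_ms, config.clock_drift_ppm
    )
    return Session(
        config=config,
        movement=movement,
        force=force,
        touch_log_device_ms=touch_device,
        tactile_times_ms=tactile_ms,
        truth=truth,
        eeg=eeg,
        montage=montage,
    )


def scaled_config(**overrides) -> SessionConfig:
    """A small fast session for tests and examples (2 min, 16 channels)."""
    base = dict(
        duration_s=220.0,
        n_goal=50,
        n_nongoal=15,
        eeg=EEGParams(n_channels=16, eeg_srate=250.0),
        seed=0,
    )
    base.update(overrides)
    return SessionConfig(**base)
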