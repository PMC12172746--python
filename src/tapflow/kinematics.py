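"""Movement-signal conditioning and behavioral event statistics.

Covers the kinematic side of the pipeline: zero-phase 1-10 Hz band-pass
of the flexion trace, event-locked movement epochs, the kinematic
similarity gate between goal and non-goal movements (median-trace
Pearson R, inclusion at R > 0.8), inter-event interval summaries, and
the ordering-bias test asking whether non-goal movements cluster just
after goal movements rather than just before.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)


@dataclass
class MovementEpochs:
    """Trials x time matrix of per-trial z-scored movement segments."""

    data: np.ndarray
    times_ms: np.ndarray
    label: str = ""

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[1] != self.times_ms.size:
            raise ValueError("epochs must be (trials, times) matching the time axis")

    def median_trace(self) -> np.ndarray:
        return np.median(self.data, axis=0)


def bandpass_movement(trace: np.ndarray, lo: float = 1.0, hi: float = 10.0,
                      srate: float = 1000.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward); removes DC."""
    if srate < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    if hi >= srate / 2 or lo <= 0 or lo >= hi:
        raise ValueError(f"invalid band ({lo}, {hi}) at srate {srate}")
    sos = butter(order, (lo, hi), btype="bandpass", fs=srate, output="sos")
    return sosfiltfilt(sos, np.asarray(trace, dtype=float))


def epoch_movement(trace: np.ndarray, events_ms: np.ndarray,
                   window_ms=(-1000.0, 1000.0), srate: float = 1000.0,
                   label: str = "") -> MovementEpochs:
    """Event-locked movement segments, z-scored per trial."""
    n = len(trace)
    k0 = int(round(window_ms[0] * srate / 1000.0))
    k1 = int(round(window_ms[1] * srate / 1000.0))
    times = np.arange(k0, k1 + 1) / srate * 1000.0
    rows = []
    for t in np.asarray(events_ms, dtype=float):
        c = int(round(t * srate / 1000.0))
        if c + k0 < 0 or c + k1 >= n:
            logger.info("movement event at %.0f ms too close to edge; dropped", t)
            continue
        seg = np.asarray(trace[c + k0 : c + k1 + 1], dtype=float)
        sd = seg.std()
        rows.append((seg - seg.mean()) / (sd if sd > 1e-15 else 1.0))
    if not rows:
        raise ValueError("no events far enough from the recording edges")
    return MovementEpochs(np.vstack(rows), times, label)


def similarity(goal: MovementEpochs, nongoal: MovementEpochs,
               r_threshold: float = 0.8) -> tuple[float, bool]:
    """Pearson R between the two median traces; include iff R > threshold."""
    if goal.data.shape[0] < 2 or nongoal.data.shape[0] < 2:
        raise ValueError("need at least 2 trials per movement class")
    a, b = goal.median_trace(), nongoal.median_trace()
    if a.std() < 1e-15 or b.std() < 1e-15:
        raise ValueError("constant median trace; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, r > r_threshold


@dataclass
class IntervalStats:
    intervals_s: np.ndarray
    bin_edges_s: np.ndarray
    counts: np.ndarray
    modes_s: np.ndarray        # interval at each local histogram maximum
    quantiles_s: dict


def interval_stats(times_ms: np.ndarray, n_bins: int = 36,
                   span_s=(0.1, 100.0)) -> IntervalStats:
    """Log-spaced inter-event interval histogram with modal intervals."""
    t = np.sort(np.asarray(times_ms, dtype=float))
    if t.size < 2:
        raise ValueError("need at least 2 events for interval statistics")
    iv = np.diff(t) / 1000.0
    edges = np.geomspace(span_s[0], span_s[1], n_bins + 1)
    counts, _ = np.histogram(iv, edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    c = counts.astype(float)
    is_mode = np.zeros(n_bins, dtype=bool)
    for i in range(n_bins):
        left = c[max(i - 1, 0)]
        right = c[min(i + 1, n_bins - 1)]
        if c[i] > 0 and c[i] >= left and c[i] >= right and (
            c[i] > left or c[i] > right
        ):
            is_mode[i] = True
    modes = centers[is_mode]
    order = np.argsort(-c[is_mode])
    qs = {q: float(np.quantile(iv, q)) for q in (0.1, 0.25, 0.5, 0.75, 0.9)}
    return IntervalStats(iv, edges, counts, modes[order], qs)


def ordering_bias(goal_by_subject: list[np.ndarray],
                  nongoal_by_subject: list[np.ndarray]):
    """Do non-goal movements sit closer after a goal movement than before?

    Per subject, each non-goal event contributes its lag to the nearest
    preceding and nearest following goal event; the paired quantities are
    the subject means of those two absolute lags.  A population paired
    t-test (preceding - following, negative t = closer to the preceding
    goal, i.e. "right after") is run across subjects.

    Returns ``(t, p, table)`` where the table has one row per retained
    subject with mean preceding / following lags in ms.
    """
    rows = []
    for s, (g, ng) in enumerate(zip(goal_by_subject, nongoal_by_subject)):
        g = np.sort(np.asarray(g, dtype=float))
        ng = np.asarray(ng, dtype=float)
        if g.size == 0 or ng.size == 0:
            logger.info("subject %d has an empty event class; excluded", s)
            continue
        j = np.searchsorted(g, ng)
        prev_lag = np.where(j > 0, ng - g[np.clip(j - 1, 0, None)], np.nan)
        next_lag = np.where(j < g.size, g[np.clip(j, None, g.size - 1)] - ng, np.nan)
        rows.append((s, float(np.nanmean(np.abs(prev_lag))),
                     float(np.nanmean(np.abs(next_lag)))))
    if len(rows) < 2:
        raise ValueError("need at least 2 subjects with both event classes")
    arr = np.asarray([(a, b) for _, a, b in rows])
    t, p = stats.ttest_rel(arr[:, 0], arr[:, 1])
    return float(t), float(p), rows
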