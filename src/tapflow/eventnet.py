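"""Movement-landmark detection and goal / non-goal classification.

A small convolutional-recurrent network is trained, per participant, to
label touchscreen interactions from the z-scored sliding integral of the
band-passed thumb-movement trace.  Its probability peaks provide the
temporal landmarks: peaks within +-100 ms of a logged touch are
goal-directed movements (true positives), peaks further than +-1 s from
every touch are non-goal-directed movements (isolated false positives),
and peaks in between are ignored.  The decision threshold is the one
maximizing the F2 score, which favors recall over precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, ConvBiLSTMClassifier, bce_loss


@dataclass(frozen=True)
class DetectorConfig:
    n_kernels: int = 100
    kernel_size: int = 9
    n_recurrent: int = 3
    hidden: int = 16
    dropout: float = 0.5
    seq_len: int = 200            # decimated samples = 2 s of raw data
    batch_size: int = 10
    max_epochs: int = 100
    patience: int = 30            # epochs without validation-TP improvement
    lr: float = 6e-3
    lr_decay: float = 0.1
    lr_patience: int = 5
    undersample_factor: int = 10
    label_pad: int = 30           # +- samples around each touch (decimated)
    integral_window_ms: float = 100.0
    min_peak_separation_ms: float = 100.0
    peak_smooth_ms: float = 110.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_kernels", "n_recurrent", "seq_len", "batch_size",
                     "max_epochs", "undersample_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.label_pad >= self.seq_len:
            raise ValueError("label pad must be smaller than the sequence length")


@dataclass
class MatchResult:
    """Partition of detected landmarks against the touch log."""

    goal_ms: np.ndarray
    non_goal_ms: np.ndarray
    ignored_ms: np.ndarray
    missed_touch_ms: np.ndarray
    threshold: float = np.nan
    f2: float = np.nan
    counts: dict = field(default_factory=dict)

    @property
    def n_landmarks(self) -> int:
        return len(self.goal_ms) + len(self.non_goal_ms) + len(self.ignored_ms)


# ---------------------------------------------------------------------------
# input preparation


def detector_input(trace: np.ndarray, srate: float = 1000.0,
                   window_ms: float = 100.0) -> np.ndarray:
    """Z-scored sliding trapezoidal integral of the (band-passed) trace.

    The integral at sample t covers the window centered on t
    (t - w/2 .. t + w/2), so a symmetric movement bump integrates to a
    peak at its apex; samples beyond the recording edges contribute zero.
    """
    x = np.asarray(trace, dtype=float)
    w = int(round(window_ms * srate / 1000.0))
    w += w % 2  # even sample count -> exactly centered kernel
    kernel = np.full(w + 1, 1.0)
    kernel[0] = kernel[-1] = 0.5
    kernel /= srate
    half = w // 2
    integ = np.convolve(
        np.concatenate([np.zeros(half), x, np.zeros(half)]), kernel,
        mode="valid")
    sd = integ.std()
    if sd < 1e-15:
        raise ValueError("integral series has zero variance; cannot z-score")
    return (integ - integ.mean()) / sd


def undersample(series: np.ndarray, labels: np.ndarray | None = None,
                factor: int = 10):
    """Keep every ``factor``-th sample; labels are block-maxed so a raw
    label anywhere inside a block survives at that decimated index."""
    series = np.asarray(series)
    dec = series[::factor]
    if labels is None:
        return dec
    labels = np.asarray(labels)
    n = len(dec)
    padded = np.zeros(n * factor, dtype=labels.dtype)
    padded[: len(labels)] = labels[: n * factor]
    return dec, padded.reshape(n, factor).max(axis=1)


def make_labels(touch_ms: np.ndarray, n_samples: int, factor: int = 10,
                pad: int = 30, srate: float = 1000.0) -> np.ndarray:
    """Binary labels on the decimated axis: 1 within +-``pad`` samples of
    each touch (overlapping pads merge)."""
    labels = np.zeros(n_samples, dtype=np.int8)
    step_ms = factor * 1000.0 / srate
    for t in np.asarray(touch_ms, dtype=float):
        i = int(np.floor(t / step_ms))
        labels[max(i - pad, 0) : min(i + pad + 1, n_samples)] = 1
    return labels


# ---------------------------------------------------------------------------
# scoring


def f_beta(tp: int, fp: int, fn: int, beta: float = 2.0) -> float:
    """F-beta from counts; beta=2 weighs recall four times precision."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == fp == fn == 0:
        raise ValueError("all counts zero; score undefined")
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return (1 + beta**2) * p * r / (beta**2 * p + r)


def _threshold_grid(probs: np.ndarray, cap: int = 1001) -> np.ndarray:
    grid = np.unique(probs)
    if grid.size > cap:
        grid = np.unique(np.quantile(probs, np.linspace(0, 1, cap)))
    return grid


def select_threshold(probs: np.ndarray, labels: np.ndarray,
                     beta: float = 2.0, cap: int = 1001):
    """Scan thresholds (all distinct predictions, capped at ``cap``
    quantiles) and return ``(threshold, best_f2)``; ties pick the lowest
    threshold.  A sample is classified 1 when its probability exceeds
    the threshold strictly."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(bool)
    grid = _threshold_grid(probs, cap)
    order = np.argsort(probs, kind="stable")
    ps = probs[order]
    ls = labels[order]
    pos_suffix = np.concatenate([np.cumsum(ls[::-1])[::-1], [0]])
    n = len(ps)
    total_pos = int(ls.sum())
    idx = np.searchsorted(ps, grid, side="right")
    tp = pos_suffix[idx]
    fp = (n - idx) - tp
    fn = total_pos - tp
    beta2 = beta**2
    with np.errstate(divide="ignore", invalid="ignore"):
        f2 = (1 + beta2) * tp / ((1 + beta2) * tp + beta2 * fn + fp)
    f2 = np.where(tp > 0, f2, 0.0)
    best = int(np.argmax(f2))  # first occurrence = lowest threshold
    return float(grid[best]), float(f2[best])


def find_peaks(probs: np.ndarray, threshold: float,
               step_ms: float = 10.0, min_separation_ms: float = 100.0,
               smooth_ms: float = 0.0) -> np.ndarray:
    """Landmark times (ms): supra-threshold local maxima of the
    probability series, at least the minimum separation apart (closer
    peaks merge to the higher apex); plateaus resolve to their center
    sample.  ``smooth_ms`` optionally box-car smooths the series first,
    which stabilizes apex positions on broad, noisy probability bumps.
    """
    from scipy.signal import find_peaks as _sp_find_peaks

    probs = np.asarray(probs, dtype=float)
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms / step_ms)))
        probs = np.convolve(probs, np.full(w, 1.0 / w), mode="same")
    masked = np.where(probs > threshold, probs, 0.0)
    if not masked.any():
        return np.empty(0)
    distance = max(1, int(round(min_separation_ms / step_ms)))
    idx, props = _sp_find_peaks(masked, height=np.nextafter(threshold, np.inf),
                                distance=distance, plateau_size=1)
    apex = (props["left_edges"] + props["right_edges"]) // 2
    return apex.astype(float) * step_ms


def classify_landmarks(landmarks_ms: np.ndarray, touch_ms: np.ndarray,
                       goal_window_ms: float = 100.0,
                       isolation_ms: float = 1000.0,
                       threshold: float = np.nan) -> MatchResult:
    """Partition landmarks into goal / non_goal / ignored.

    Greedy nearest-first one-to-one matching: each touch is claimed by at
    most one landmark within the +-100 ms window (goal).  Unmatched
    landmarks further than 1 s from every touch are non-goal; everything
    else — including extra landmarks near an already-claimed touch — is
    ignored.  Unmatched touches are misses (FN).
    """
    lm = np.sort(np.asarray(landmarks_ms, dtype=float))
    touch = np.sort(np.asarray(touch_ms, dtype=float))
    pairs = []
    for i, t in enumerate(lm):
        if touch.size == 0:
            break
        j = int(np.searchsorted(touch, t))
        for jj in (j - 1, j):
            if 0 <= jj < touch.size:
                d = abs(t - touch[jj])
                if d <= goal_window_ms:
                    pairs.append((d, i, jj))
    lm_used = np.zeros(lm.size, dtype=bool)
    touch_used = np.zeros(touch.size, dtype=bool)
    for d, i, j in sorted(pairs):
        if not lm_used[i] and not touch_used[j]:
            lm_used[i] = touch_used[j] = True
    goal, non_goal, ignored = [], [], []
    for i, t in enumerate(lm):
        if lm_used[i]:
            goal.append(t)
            continue
        d = np.abs(touch - t).min() if touch.size else np.inf
        if d > isolation_ms:
            non_goal.append(t)
        else:
            ignored.append(t)
    missed = touch[~touch_used]
    tp, fp, fn = len(goal), len(non_goal), len(missed)
    f2 = f_beta(tp, fp, fn) if (tp + fp + fn) else np.nan
    return MatchResult(
        np.asarray(goal), np.asarray(non_goal), np.asarray(ignored),
        np.asarray(missed), threshold=threshold, f2=f2,
        counts={"tp": tp, "fp": fp, "fn": fn},
    )


# ---------------------------------------------------------------------------
# training


def train_detector(series: np.ndarray, labels: np.ndarray,
                   config: DetectorConfig = DetectorConfig()):
    """Train the conv+BiLSTM labeler on the decimated input series.

    Contiguous 80/10/10 split; batches of random ``seq_len`` windows from
    the training block; the validation block is scored unshuffled after
    every epoch by counting true-positive samples at p > 0.5.  Early
    stopping and learning-rate decay both key on that count.

    Returns ``(model, log)`` with per-epoch validation TP counts.
    """
    series = np.asarray(series, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = len(series)
    n_train = int(round(0.8 * n))
    n_val = int(round(0.1 * n))
    if labels[:n_train].sum() == 0:
        raise ValueError("no positive labels in the training split")
    rng = np.random.default_rng(config.seed)
    model = ConvBiLSTMClassifier(
        n_kernels=config.n_kernels, kernel_size=config.kernel_size,
        hidden=config.hidden, n_layers=config.n_recurrent,
        dropout=config.dropout, seed=config.seed,
    )
    opt = Adam(model.flat_params(), lr=config.lr)
    L = config.seq_len
    val_x = series[n_train : n_train + n_val]
    val_y = labels[n_train : n_train + n_val]
    n_batches = max(1, n_train // L)
    best_tp, wait, lr_wait = -1, 0, 0
    best_state = None
    log = []
    for epoch in range(config.max_epochs):
        for _ in range(n_batches):
            starts = rng.integers(0, n_train - L, config.batch_size)
            xb = np.stack([series[s : s + L] for s in starts])
            yb = np.stack([labels[s : s + L] for s in starts])
            prob, cache = model.forward(xb, train=True, rng=rng)
            _, dprob = bce_loss(prob, yb)
            grads = model.backward(cache, dprob)
            opt.step(model.flat_params(),
                     {f"{l}.{p}": grads[l][p] for l in grads for p in grads[l]})
        val_prob = predict_series(model, val_x, L)
        tp = int(np.sum((val_prob > 0.5) & (val_y > 0.5)))
        log.append(tp)
        if tp > best_tp:
            best_tp, wait, lr_wait = tp, 0, 0
            best_state = {k: a.copy() for k, a in model.flat_params().items()}
        else:
            wait += 1
            lr_wait += 1
            if lr_wait >= config.lr_patience:
                opt.lr *= config.lr_decay
                lr_wait = 0
            if wait >= config.patience:
                break
    if best_state is not None:
        for k, a in model.flat_params().items():
            a[...] = best_state[k]
    return model, log


def predict_series(model, series: np.ndarray, seq_len: int = 200) -> np.ndarray:
    """Probability for every sample of a long series, tiled in windows."""
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n == 0:
        return np.empty(0)
    n_pad = (-n) % seq_len
    padded = np.concatenate([series, np.zeros(n_pad)])
    wins = padded.reshape(-1, seq_len)
    prob = model.predict(wins)
    return prob.reshape(-1)[:n]


def detect_session(movement_bandpassed: np.ndarray, touch_lab_ms: np.ndarray,
                   config: DetectorConfig = DetectorConfig(),
                   srate: float = 1000.0) -> tuple[MatchResult, np.ndarray]:
    """End-to-end detection on one session.

    Band-passed movement trace in, :class:`MatchResult` out.  The F2
    threshold scan runs over the model's predictions on the full series.
    """
    integ = detector_input(movement_bandpassed, srate, config.integral_window_ms)
    dec = undersample(integ, factor=config.undersample_factor)
    labels = make_labels(touch_lab_ms, len(dec), config.undersample_factor,
                         config.label_pad, srate)
    model, _ = train_detector(dec, labels, config)
    prob = predict_series(model, dec, config.seq_len)
    thr, _ = select_threshold(prob, labels)
    step_ms = config.undersample_factor * 1000.0 / srate
    landmarks = find_peaks(prob, thr, step_ms, config.min_peak_separation_ms,
                           config.peak_smooth_ms)
    result = classify_landmarks(landmarks, touch_lab_ms, threshold=thr)
    return result, prob
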