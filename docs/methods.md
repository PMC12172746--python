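# Methods

`tapflow` analyzes EEG time-locked to thumb movements during natural
smartphone use. Its scientific core is the contrast between two classes
of kinematically similar movements: **goal-directed** movements that
produce a logged touchscreen interaction, and **non-goal-directed**
movements that do not. Because no public recordings accompany the
procedure, the package ships a first-class synthetic-session generator
with complete ground truth; every stage of the pipeline is validated by
recovering what the generator injected.

## Pipeline

1. **Clock alignment** (`clocksync`). The touch log is timestamped by
   the phone's operating system; the laboratory clock drives the EEG,
   force and movement sensors. No trigger can be injected into the
   phone, so alignment is data-driven: a regressor maps movement-sensor
   features to the force-sensor trace, and the constant delay between
   logged touches and predicted-force peaks is estimated by normalized
   cross-correlation and subtracted.
   - Features: the raw 1 kHz movement value plus 100 equally weighted
     10 ms moving averages, taken at 1 ms lags (columns k = 1..100 hold
     the average evaluated k−1 ms earlier; edges replicated). The lag
     reading of "100 extracted moving averages" is a documented
     interpretation — a multi-scale reading is equally consistent with
     the phrase, but lags make the 101-dimensional input well defined.
   - Splits are contiguous 80/10/10 (train/validation/test);
     normalization statistics come from the training block only, and a
     test asserts no leakage.
   - Two regressors share one contract: a ridge regression on the
     windowed features (default; deterministic, seconds to fit) and a
     2-layer bidirectional LSTM trained on batches of 10 random
     1000-sample windows. Reported MSEs are on the z-scored force, so
     1.0 is the mean-predictor baseline.
   - Delay search: predicted force and the touch impulse train are
     Gaussian-smoothed (σ = 25 ms), z-scored and cross-correlated over
     ±5 s at 1 ms resolution. Subjects whose normalized correlation
     peak falls below 0.2 are flagged misaligned and excluded; the
     threshold is explicit and configurable; visual inspection of
     misalignment is deliberately avoided.

2. **Movement-landmark detection** (`eventnet`). A per-participant
   classifier labels touchscreen interactions from kinematics alone:
   input is the z-scored sliding trapezoidal integral (100 ms window,
   centered) of the 1–10 Hz band-passed flexion trace, undersampled
   ×10; labels are 1 within ±30 (decimated) samples of a touch. The
   model is a 1-D convolution (100 kernels) feeding three bidirectional
   LSTM layers with 0.5 dropout between them and a sigmoid unit, trained
   with binary cross-entropy on batches of 10 random 200-sample windows
   (one epoch = train length / 200 batches), early-stopped on the
   validation true-positive count (patience 30) with learning-rate decay
   ×0.1 after 5 stale epochs. The networks are implemented in NumPy
   with manual backpropagation (gradients are finite-difference checked
   in the test suite) so training is single-threaded and bit-reproducible
   from a seed; the LSTM hidden size (16) is a package choice sized for
   one CPU core.
   - The decision threshold maximizes the sample-level F2 score over
     all distinct predicted values (capped at 1001 quantiles), F2
     because recall matters four times as much as precision here: a
     missed movement is lost data, a false positive is — by design —
     a candidate non-goal movement.
   - Landmarks are supra-threshold local maxima at least 100 ms apart
     (plateaus resolve to their center). Because the optimal
     probability is flat across the ±300 ms label window, apex
     positions on the raw trace are noise-driven; a 110 ms box-car
     smoothing (configurable) stabilizes them.
   - Classification: a landmark within ±100 ms of a touch is
     goal-directed (greedy nearest-first, one landmark per touch);
     further than ±1 s from every touch, non-goal-directed; in
     between, ignored. Event-level F2 is computed from goal (TP),
     non-goal (FP) and missed-touch (FN) counts; ignored landmarks are
     excluded from scoring.

3. **Kinematic gate and behavior** (`kinematics`). Movement epochs are
   z-scored per trial; a participant enters the EEG contrast only when
   the Pearson correlation between the median goal and median non-goal
   traces exceeds 0.8 — the point of the design is to compare movements
   that look the same and differ only in outcome. Inter-event-interval
   summaries use log-spaced histograms. The ordering-bias statistic
   takes, per subject, the mean absolute lag from each non-goal event
   to the nearest preceding and nearest following goal event, and runs
   a population paired t-test on the two means (negative t = non-goal
   events sit closer after a goal). The paired construction is a
   documented package choice; only the test family is fixed.

4. **EEG preprocessing** (`eegprep`). High-impedance channels
   (>10 kΩ) are replaced by spherical-spline interpolation (via mne);
   more than 25% bad channels, or a bad channel with no neighbor within
   twice the median inter-electrode distance, is an error. Band-pass
   presets: 0.5–30 Hz for ERPs, 0.5–45 Hz for spectral analysis,
   1–45 Hz for the tactile probe (zero-phase Butterworth, order 4).
   Epochs are −2..+2 s around the event with the −2..−1.5 s baseline
   mean subtracted per trial and channel; trials crossing ±80 μV are
   rejected; a participant is included only with more than 50 surviving
   trials per movement class. Tactile stimulations are assigned to the
   movement class with a landmark within ±500 ms (ambiguous ones are
   dropped) and epoched −100..+400 ms with a −100..−25 ms baseline —
   the post-stimulus extent is a package decision: a purely pre-event
   window cannot contain the somatosensory response it is meant to
   measure. Blink removal is a no-op hook (the generator makes
   no blinks); any `EEGRecording -> EEGRecording` cleaner can be
   plugged in.

5. **Time–frequency analysis** (`timefreq`). Morlet wavelet power at
   1–40 Hz with cycles(f) = (f/f_min)^0.7 — one cycle at the lowest
   frequency, widening with an exponent of 0.7. This is one reading of
   an EEGLAB-style two-parameter cycle rule; a linear-growth rule is
   available behind the same switch. Samples within three wavelet
   standard deviations of an epoch edge are flagged invalid. ERSP is
   per-trial dB relative to the baseline window, with the reference
   taken as the mean *log* power (geometric mean): with stochastic
   single-trial power, an arithmetic-mean reference biases every cell
   by about −2.5 dB (Jensen's inequality), which would make one-sample
   tests against 0 dB reject everywhere; the log-domain reference is
   exactly unbiased under stationarity and identical for deterministic
   amplitude changes (amplitude ×0.5 → −6.02 dB). Band averages use
   inclusive edges; presets alpha 8–12, beta 12–30, gamma 30–40 Hz
   (alpha/gamma edges are package defaults).

6. **Robust statistics** (`robuststat`). Cell-wise inference uses 20%
   trimmed means: the one-sample statistic is Tukey–McLaughlin,
   T = (trimmed mean − μ₀)/SE with SE = s_w/((1−2g/n)√n) from the
   winsorized variance and df = h−1 (g = ⌊trim·n⌋, h = n−2g); paired
   designs test the differences. At trim = 0 both reduce to the
   classical t-tests to 1e−10 (asserted). Multiple comparisons are
   controlled by spatiotemporal clustering: cells with p < α (0.05)
   are grouped — adjacent along time (and frequency) within a channel,
   or across channels within the montage adjacency (default radius
   1.3 × median nearest-neighbor distance) — positive and negative
   statistics separately; cluster mass is Σ|T|. The null is built by
   resampling units with replacement from per-cell trimmed-mean-centered
   data, recording each resample's maximum cluster mass (1000 bootstraps
   by default); a cluster is significant when the proportion of
   bootstrap maxima at or above its mass falls below α. The
   hierarchical path fits per-subject OLS with a condition indicator
   and the detector peak probability as a trial covariate, then runs
   cluster-corrected one-sample tests on the subject coefficient maps;
   beta-band-only analyses restrict the spectral axis to 12–30 Hz.

## The synthetic generator

The generator (`synthio`) encodes the study conditions rather than
mimicking raw EEG in detail:

- **Goal events** form a renewal stream whose inter-touch intervals are
  log-normal with mode ≈ 1 s, mixed with an 18% long-pause component
  (mode ≈ 7 s). The pauses serve two purposes: natural usage contains
  breaks, and — more importantly — non-goal events must lie more than
  1 s from *every* touch to be classifiable at all, which is impossible
  inside runs of ~1 s inter-touch intervals.
- **Non-goal events** are placed inside inter-goal gaps at ≥ 1.1 s
  margins, preferentially just after the preceding goal event with
  probability 0.7 (configurable bias). Slots inside a gap are 1 s
  apart, which produces the short inter-event mode near 1 s; the pause
  spacing produces the secondary mode near 10 s. The interval family is
  a stand-in: only the modal structure and the after-goal bias are
  treated as conditions.
- **Kinematics**: every movement is a Gaussian-windowed asymmetric
  raised cosine (rise 0.6 w, decay 1.4 w, w = 0.4 s jittered ±15%),
  apex exactly at the event time, drawn from one shape family for both
  classes so the median-trace correlation exceeds 0.9 at default noise.
  Only goal events add a force pulse (50 ms raised cosine at the apex).
- **EEG**: per-channel 1/f background (exponent 1.0, 10 μV rms) plus an
  ongoing 16–24 Hz oscillation (4 μV rms). Goal events inject a slow
  contralateral positivity (−700..0 ms, +2 μV), a contralateral
  negativity (−300..+200 ms, −4 μV), an occipital negativity
  (+200..+450 ms, −3 μV), a fronto-central positivity (+500..+700 ms,
  +3 μV), and multiply the beta envelope by a −0.5-deep Hann well over
  −1.2..+0.5 s with a +0.4 rebound over +0.4..+0.7 s. Non-goal events
  get the same slow positivity, the negativity damped to 0.3×, a
  fronto-central negativity at +200..+280 ms, and a shallower,
  shorter beta well (−0.35, −0.35..+0.45 s). Tactile triggers
  (uniform 0.75–1 s intervals) add an early contralateral
  somatosensory deflection of identical amplitude regardless of the
  coinciding movement class. Additive templates reproduce exactly at
  zero noise; with templates disabled the band-averaged ERSP over
  random events stays within ±0.5 dB.
- **Montage**: a Fibonacci-lattice cap of n quasi-equidistant
  electrodes (default 64) with named groups (left/right sensorimotor,
  occipital, fronto-central, mid-frontal) assigned by proximity to
  canonical landmarks; commercial equidistant caps do not share a
  standard coordinate set, so the lattice stands in for any of them.
- **Clocks**: the touch log is exported at t_device = t_lab + offset +
  drift·t_lab (default offset 350 ms, drift 0).

What the generator does *not* emulate: blinks and EMG, volume-conducted
spatial mixing beyond group placement, app content, posture. Passing
tests therefore demonstrate that the pipeline recovers what it is
pointed at under realistic noise and event statistics — not that it is
robust to every artifact of real recordings.

## Problem sizes

Default scales are chosen so a full validation runs on one CPU core:
sessions of 20 minutes with ~300 goal / 100 non-goal events for
detector work (the package's "default session" scale); 2–4 minute,
16-channel, 250 Hz sessions for alignment and EEG recovery cohorts
(24 subjects for ERP recovery, 12 for spectral); bootstrap
cluster correction at n_boot = 200 in simulations (the analysis default
stays 1000). Detector training on synthetic sessions converges within
a handful of epochs, so validation runs cap `max_epochs` at 5–8; the
configuration default remains the full 100-epoch/patience-30 schedule.

## Numerical choices and degenerate inputs

- All randomness flows from `numpy.random.default_rng` seeds; identical
  configuration + seed reproduces sessions, trained weights and
  bootstrap masks bit-for-bit (single-threaded).
- Zero-variance cells in dense statistic maps: all-equal-to-μ₀ cells
  get T = 0, p = 1; constant cells away from μ₀ get a capped extreme
  statistic and p = 0. Scalar API calls raise instead.
- F2 ties select the lowest threshold; probability plateaus resolve to
  their center sample; greedy landmark matching is nearest-first and
  one-to-one per touch.
- Filters are zero-phase (forward–backward) so apex latencies move by
  less than 5 ms in-band; band edges at or above Nyquist are errors.
- Epochs overlapping a recording edge are dropped with a log entry;
  an empty result is an error, not an empty container.

## Known limitations

- **Bootstrap cluster correction is conservative.** Resampling whole
  units couples the effective degrees of freedom of all cells in a
  resample, so the null distribution of the maximum cluster mass is
  stochastically larger than the observed one even under iid noise;
  measured family-wise error on 24×16×200 null tensors is below 1%
  at a nominal α = 0.05 (per-cell calibration is exact). The
  correction therefore controls false positives with reduced power —
  a property inherited from the mass-univariate bootstrap family this
  implementation follows. A sign-flip permutation null would be exact
  for symmetric one-sample problems but is a different procedure, out
  of scope here.
- Detector recall on dense event streams is modest (event-level F2 in
  the 0.3–0.5 range at default scales) because neighboring ±300 ms
  label windows overlap; the goal/non-goal *landmark quality* — which
  is what the EEG contrast consumes — remains high (≥90% of goal
  landmarks within ±100 ms of a touch, ≥80% of injected non-goal
  bumps recovered).
- The drift term of the device clock is modeled by the generator but
  only the constant delay is estimated; slope estimation is off by
  default and untested against drifting sessions.
- The tactile epoch window and the first-level covariate construction
  are package decisions where the source procedure is underspecified;
  both are configurable.
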