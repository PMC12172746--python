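"""Generate a synthetic smartphone-usage session and inspect its ground truth.

A session bundles four synchronized streams: a touch log on the shifted
device clock, 1 kHz thumb-flexion and force traces, tactile-stimulation
triggers, and multichannel EEG carrying the injected event-locked
components.
"""

import numpy as np

from tapflow import synthio

cfg = synthio.scaled_config(seed=7, clock_offset_ms=420.0)
session = synthio.simulate_session(cfg)
truth = session.truth

print(f"duration           : {cfg.duration_s:.0f} s at {cfg.srate:.0f} Hz")
print(f"goal events        : {truth.true_touch_times_lab.size}")
print(f"non-goal events    : {truth.true_nongoal_times_lab.size}")
print(f"tactile triggers   : {truth.tactile_times_ms.size}")
print(f"injected offset    : {truth.clock_offset_ms:.0f} ms")
print(f"EEG                : {session.eeg.n_channels} channels at "
      f"{session.eeg.srate:.0f} Hz, rms {session.eeg.data.std():.1f} uV")

# every non-goal event is isolated: >1 s from any touch, so a detector
# can recover it as a false positive rather than an ambiguous case
d = np.abs(truth.true_nongoal_times_lab[:, None]
           - truth.true_touch_times_lab[None, :]).min(axis=1)
print(f"nearest goal from any non-goal event: {d.min():.0f} ms (always >1000)")
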