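"""Generator properties: event streams, traces, clocks, injected EEG."""

import numpy as np
import pytest
from scipy import stats

from tapflow import synthio
from tapflow.montage import Montage
from tapflow.synthio import (
    EffectTemplate,
    EEGParams,
    PackingError,
    SessionConfig,
    make_eeg,
    make_events,
    make_movement_trace,
    make_tactile_triggers,
    scaled_config,
    shift_to_device_clock,
    shift_to_lab_clock,
)


class TestMontage:
    def test_positions_unique_and_on_head_sphere(self):
        m = Montage(64)
        r = np.linalg.norm(m.positions, axis=1)
        assert np.allclose(r, 0.09, atol=1e-9)
        assert len({tuple(p) for p in np.round(m.positions, 9)}) == 64

    @pytest.mark.parametrize("n", [16, 32, 64])
    def test_named_groups_cover_required_regions(self, n):
        m = Montage(n)
        for g in ("left_sensorimotor", "right_sensorimotor", "occipital",
                  "fronto_central", "mid_frontal"):
            assert len(m.groups[g]) >= 2
        # contralateral groups sit on opposite sides of the midline
        lx = [m.positions[m.index(c), 0] for c in m.groups["left_sensorimotor"]]
        rx = [m.positions[m.index(c), 0] for c in m.groups["right_sensorimotor"]]
        assert max(lx) < 0 < min(rx)


class TestEvents:
    def test_no_goals_gives_unbiased_nongoal_stream(self):
        cfg = SessionConfig(duration_s=400, n_goal=0, n_nongoal=30, seed=1)
        goal, nongoal = make_events(cfg)
        assert goal.size == 0
        assert nongoal.size == 30
        assert np.all(np.diff(nongoal) > 0)

    def test_goal_intervals_mode_near_one_second(self):
        cfg = SessionConfig(duration_s=31000, n_goal=10000, seed=2, n_nongoal=0)
        goal, _ = make_events(cfg)
        isi = np.diff(goal) / 1000.0
        hist, edges = np.histogram(np.log10(isi), bins=40)
        mode = 10 ** ((edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2)
        assert 0.7 < mode < 1.5
        assert isi.min() >= cfg.movement.refractory_s - 1e-9

    def test_after_goal_bias_fraction_matches_setting(self):
        fracs = []
        for seed in range(5):
            cfg = SessionConfig(duration_s=900, n_goal=200, n_nongoal=60,
                                nongoal_after_bias=0.7, seed=seed)
            goal, nongoal = make_events(cfg)
            j = np.searchsorted(goal, nongoal)
            prev = np.where(j > 0, nongoal - goal[np.clip(j - 1, 0, None)], np.inf)
            nxt = np.where(j < goal.size,
                           goal[np.clip(j, None, goal.size - 1)] - nongoal, np.inf)
            fracs.append(np.mean(prev < nxt))
        assert abs(np.mean(fracs) - 0.7) < 0.08

    def test_nongoal_events_isolated_from_every_goal(self):
        goal, nongoal = make_events(SessionConfig(seed=3))
        d = np.abs(nongoal[:, None] - goal[None, :]).min(axis=1)
        assert d.min() > 1000.0

    def test_infeasible_packing_names_the_limiting_parameter(self):
        with pytest.raises(PackingError, match="n_goal"):
            make_events(SessionConfig(duration_s=60, n_goal=500, seed=0))
        with pytest.raises(PackingError, match="n_nongoal"):
            make_events(SessionConfig(duration_s=120, n_goal=30, n_nongoal=200,
                                      seed=0))

    def test_identical_seed_reproduces_session_bit_for_bit(self):
        a = synthio.simulate_session(scaled_config(seed=7))
        b = synthio.simulate_session(scaled_config(seed=7))
        assert np.array_equal(a.movement, b.movement)
        assert np.array_equal(a.force, b.force)
        assert np.array_equal(a.eeg.data, b.eeg.data)
        assert np.array_equal(a.touch_log_device_ms, b.touch_log_device_ms)


class TestTactile:
    def test_count_bounds_for_ten_seconds(self):
        for seed in range(10):
            t = make_tactile_triggers(10.0, seed=seed)
            assert 10 <= t.size <= 13

    def test_intervals_uniform_three_quarters_to_one_second(self):
        t = make_tactile_triggers(9000.0, seed=1)
        iv = np.diff(t) / 1000.0
        assert iv.min() >= 0.75 - 1e-3 and iv.max() <= 1.0 + 1e-3
        assert abs(iv.mean() - 0.875) < 0.01  # mean of U(0.75, 1)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            make_tactile_triggers(0.5)


class TestMovementTrace:
    def test_force_pulse_cotimed_with_flexion_apex(self):
        cfg = SessionConfig(
            duration_s=20, n_goal=1, n_nongoal=0, seed=0,
            movement=synthio.MovementParams(noise_rms=0.0, force_noise_rms=0.0,
                                            width_jitter=0.0, amp_jitter=0.0))
        goal, _ = make_events(cfg)
        mov, force = make_movement_trace(goal, np.empty(0), cfg)
        assert abs(int(np.argmax(mov)) - int(np.argmax(force))) <= 1
        assert abs(np.argmax(mov) - goal[0]) <= 1  # 1 kHz: sample == ms

    def test_negative_amplitude_rejected(self):
        cfg = SessionConfig(movement=synthio.MovementParams(amplitude=-1.0))
        with pytest.raises(ValueError):
            make_movement_trace(np.array([5000.0]), np.empty(0), cfg)

    def test_goal_and_nongoal_peak_amplitudes_indistinguishable(self):
        cfg = SessionConfig(duration_s=900, seed=4)
        goal = np.arange(100) * 4000.0 + 5000.0
        nongoal = goal + 2000.0
        mov, _ = make_movement_trace(goal, nongoal, cfg)
        gp = [mov[int(t) - 200 : int(t) + 200].max() for t in goal]
        np_ = [mov[int(t) - 200 : int(t) + 200].max() for t in nongoal]
        assert stats.ks_2samp(gp, np_).pvalue > 0.05

    def test_force_pulses_only_at_goal_events(self, small_session):
        s = small_session
        force = s.force
        pulse_idx = np.flatnonzero(force > 0.5)
        goal = s.truth.true_touch_times_lab
        nongoal = s.truth.true_nongoal_times_lab
        for i in pulse_idx:
            assert np.abs(goal - i).min() <= 60
        if pulse_idx.size and nongoal.size:
            d = np.abs(nongoal[:, None] - pulse_idx[None, :]).min()
            assert d > 1000


class TestClockMapping:
    def test_identity_and_pure_offset(self):
        t = np.array([0.0, 1000.0, 50000.0])
        assert np.array_equal(shift_to_device_clock(t, 0.0, 0.0), t)
        assert np.array_equal(shift_to_device_clock(t, 350.0), t + 350.0)

    def test_drift_closed_form(self):
        t = np.array([3600_000.0])  # one hour
        out = shift_to_device_clock(t, 350.0, drift_ppm=100.0)
        assert np.isclose(out[0], 3600_000.0 + 350.0 + 360.0)

    def test_round_trip_is_exact(self):
        t = np.linspace(0, 2e6, 57)
        back = shift_to_lab_clock(shift_to_device_clock(t, 123.4, 57.0),
                                  123.4, 57.0)
        assert np.allclose(back, t, atol=1e-9)

    def test_extreme_drift_rejected(self):
        with pytest.raises(ValueError):
            shift_to_device_clock(np.array([1.0]), 0.0, drift_ppm=1500.0)


class TestEEGTemplates:
    def test_zero_noise_eeg_reproduces_template_sum_exactly(self):
        cfg = scaled_config(
            duration_s=30, n_goal=1, n_nongoal=0,
            eeg=EEGParams(n_channels=16, eeg_srate=250.0, noise_rms_uv=0.0,
                          beta_rms_uv=0.0))
        rec, truth = make_eeg(np.array([15000.0]), np.empty(0), np.empty(0),
                              cfg)
        m = Montage(16)
        srate = 250.0
        k = np.arange(-500, 501)
        times = k / srate * 1000.0
        c = int(round(15000.0 / 1000.0 * srate))
        for ch_name in set(sum((list(t.channels)
                                for t in truth.templates["goal"]), [])):
            ch = rec.ch_names.index(ch_name)
            expect = np.zeros(times.shape)
            for tpl in truth.templates["goal"]:
                if ch_name in tpl.channels:
                    expect += tpl.waveform(times)
            got = rec.data[ch, c + k[0] : c + k[-1] + 1]
            assert np.allclose(got, expect, atol=1e-12)

    def test_template_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="epoch range"):
            EffectTemplate("too_late", ("ch01",), (1500.0, 2500.0), 1.0)

    def test_depth_bounds_enforced(self):
        with pytest.raises(ValueError):
            EffectTemplate("deep", ("ch01",), (0.0, 100.0), band=(12, 30),
                           depth=-1.5)

    def test_nongoal_attenuation_recovered_by_template_fit(self):
        cfg = scaled_config(
            duration_s=215, n_goal=40, n_nongoal=40,
            eeg=EEGParams(n_channels=16, eeg_srate=250.0, noise_rms_uv=2.0,
                          beta_rms_uv=0.0, nongoal_attenuation=0.3))
        # isolated, regularly spaced events so neighboring-event components
        # cannot leak into the fit window
        goal = 5000.0 + 5000.0 * np.arange(40)
        nongoal = goal + 2500.0
        rec, truth = make_eeg(goal, nongoal, np.empty(0), cfg)
        goal_t = truth.templates["goal"]
        neg = next(t for t in goal_t if t.name == "motor_negativity")
        ramp = next(t for t in goal_t if t.name == "premovement_positivity")
        ch = rec.ch_names.index(neg.channels[0])
        srate = 250.0
        win = np.arange(-250, 126)
        times = win / srate * 1000.0
        X = np.column_stack([neg.envelope(times), ramp.envelope(times),
                             np.ones(times.size)])

        def fitted_amp(events):
            rows = []
            for ev in events:
                c = int(round(ev / 1000.0 * srate))
                rows.append(rec.data[ch, c + win[0] : c + win[-1] + 1])
            beta, *_ = np.linalg.lstsq(X, np.mean(rows, axis=0), rcond=None)
            return beta[0]

        ratio = (fitted_amp(truth.true_nongoal_times_lab)
                 / fitted_amp(truth.true_touch_times_lab))
        assert abs(ratio - 0.3) < 0.1

    def test_spectral_null_without_templates(self):
        from tapflow import eegprep, timefreq

        cfg = scaled_config(seed=4, n_goal=0, n_nongoal=0)
        s = synthio.simulate_session(cfg)
        rng = np.random.default_rng(0)
        ev = rng.uniform(2500, cfg.duration_s * 1000 - 2500, 200)
        rec = eegprep.bandpass_eeg(s.eeg, "spectral")
        epo = eegprep.epoch(rec, ev)
        spec = timefreq.morlet_cwt(epo, np.arange(12.0, 31.0, 3.0), decim=4)
        er = timefreq.ersp(spec, (-2000, -1500))
        band, _ = timefreq.band_average(er, "beta")
        assert abs(band.mean()) < 0.5
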