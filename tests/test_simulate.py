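"""Simulator: protocol structure, signal statistics, dropouts, determinism."""
import numpy as np
import pytest

import sleepderiv as sd
from sleepderiv import GenerationError, ValidationError
from sleepderiv.series import SLEEP, WAKE


class TestProtocol:
    def test_72h_protocol_has_36_wake_and_36_nap_blocks(self):
        cfg = sd.SimConfig(missing_fraction=0.0)
        events, states = sd.generate_protocol(cfg, seed=0)
        naps = events.naps()
        assert len(naps) == 36
        assert int(np.sum(events.event == "lights_on")) == 37  # final one closes the last nap
        assert states.n_epochs == 72 * 120

    def test_zero_waso_zero_latency_naps_are_pure_sleep(self):
        cfg = sd.SimConfig(
            duration_h=6.0, waso_fraction=0.0, sleep_latency_mean_min=0.0,
            missing_fraction=0.0,
        )
        events, states = sd.generate_protocol(cfg, seed=1)
        for nap in events.naps():
            assert nap.onset == nap.lights_off
            sel = (states.epoch_start_s >= nap.lights_off) & (
                states.epoch_start_s < nap.lights_on
            )
            assert np.all(states.state[sel] == SLEEP)

    def test_states_consistent_with_events(self):
        cfg = sd.profile_config("S12", duration_h=12.0)
        events, states = sd.generate_protocol(cfg, seed=3)
        for nap in events.naps():
            # before onset (or everywhere if no onset) the subject is awake
            end = nap.onset if nap.onset is not None else nap.lights_on
            sel = (states.epoch_start_s >= nap.lights_off) & (states.epoch_start_s < end)
            assert np.all(states.state[sel] == WAKE)
            if nap.onset is not None:
                i0 = int(np.searchsorted(states.epoch_start_s, nap.onset))
                assert states.state[i0] == SLEEP  # onset is the first sleep epoch

    def test_waso_calibration_recovers_profile_fraction(self):
        # >=200 naps; simulated per-nap mean within 3 SE of the configured value
        cfg = sd.profile_config("S10", duration_h=420.0, missing_fraction=0.0)
        events, states = sd.generate_protocol(cfg, seed=7)
        ws = sd.compute_waso_stats(states, events)
        assert ws.n_naps >= 200
        se = ws.sd_pct / np.sqrt(ws.n_naps)
        assert abs(ws.mean_pct - 5.6) < 3 * se

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            sd.SimConfig(duration_h=-1)
        with pytest.raises(ValidationError):
            sd.SimConfig(missing_fraction=1.0)
        with pytest.raises(ValidationError):
            sd.SimConfig(rri_mean_awake=100.0)
        with pytest.raises(ValidationError):
            sd.SimConfig(rri_sd_awake=900.0, rri_mean_awake=800.0)


class TestRri:
    def test_zero_noise_zero_drift_gives_state_means(self, wake_only_config):
        cfg_flat = sd.SimConfig(
            duration_h=3.0, wake_block_min=180.0, drift_amplitude_ms=0.0,
            rri_sd_awake=0.0, rri_sd_sleep=0.0, missing_fraction=0.0,
        )
        _, states = sd.generate_protocol(cfg_flat)
        beats = sd.generate_rri(states, cfg_flat)
        assert np.allclose(beats.rri, cfg_flat.rri_mean_awake)

    def test_zero_noise_piecewise_constant_between_transitions(self):
        cfg = sd.SimConfig(
            duration_h=4.0, drift_amplitude_ms=0.0, rri_sd_awake=0.0,
            rri_sd_sleep=0.0, waso_fraction=0.0, sleep_latency_mean_min=0.0,
            missing_fraction=0.0,
        )
        _, states = sd.generate_protocol(cfg, seed=2)
        beats = sd.generate_rri(states, cfg)
        # away from the 60-s transition ramps the RRI equals a state mean
        means = {cfg.rri_mean_awake, cfg.rri_mean_sleep}
        transition_t = [t for t in states.epoch_start_s[np.r_[False, np.diff(
            states.state == SLEEP).astype(bool)]]]
        far = np.ones(len(beats), dtype=bool)
        for tt in transition_t:
            far &= np.abs(beats.beat_times - tt) > 90.0
        vals = np.unique(np.round(beats.rri[far], 9))
        assert set(vals) <= means

    def test_wake_mean_within_three_standard_errors(self, wake_only_config, wake_only_beats):
        cfg, beats = wake_only_config, wake_only_beats
        n = len(beats)
        assert n >= 10_000
        rho, sd_ = cfg.ar_coeff, cfg.rri_sd_awake
        # variance of the mean of an AR(1) sample, long-series form
        se = sd_ * np.sqrt((1 + rho) / ((1 - rho) * n))
        assert abs(beats.rri.mean() - cfg.rri_mean_awake) < 3 * se

    def test_lag1_autocorrelation_matches_ar_coefficient(self, wake_only_config, wake_only_beats):
        x = wake_only_beats.rri - wake_only_beats.rri.mean()
        r1 = float(x[1:] @ x[:-1]) / float(x @ x)
        assert abs(r1 - wake_only_config.ar_coeff) < 0.05

    def test_time_rri_conservation(self, wake_only_beats):
        b = wake_only_beats
        assert np.allclose(np.diff(b.beat_times), b.rri[:-1] / 1000.0, atol=1e-9)
        b.validate()

    def test_impossible_parameters_raise_generation_error(self):
        cfg = sd.SimConfig(
            duration_h=1.0, wake_block_min=60.0, rri_mean_awake=300.0,
            rri_sd_awake=150.0, drift_amplitude_ms=0.0, missing_fraction=0.0,
        )
        _, states = sd.generate_protocol(cfg)
        with pytest.raises(GenerationError, match="rri"):
            sd.generate_rri(states, cfg, seed=0)


class TestRc:
    def test_zero_noise_equals_state_means_and_ordering(self):
        cfg = sd.SimConfig(
            duration_h=4.0, rc_sd_awake=0.0, rc_sd_sleep=0.0,
            waso_fraction=0.0, sleep_latency_mean_min=0.0, missing_fraction=0.0,
        )
        _, states = sd.generate_protocol(cfg, seed=4)
        resp = sd.generate_rc(states, cfg)
        # values are the two state means, joined by 60-s transition ramps
        assert resp.rc.min() >= cfg.rc_mean_sleep - 1e-9
        assert resp.rc.max() <= cfg.rc_mean_awake + 1e-9
        assert np.any(np.isclose(resp.rc, cfg.rc_mean_awake))
        assert np.any(np.isclose(resp.rc, cfg.rc_mean_sleep))

    def test_sleep_rc_below_wake_rc(self, short_recording):
        rec = short_recording
        sec_state = np.repeat(rec.states.state == SLEEP, 30)[: len(rec.resp)]
        assert rec.resp.rc[sec_state].mean() < rec.resp.rc[~sec_state].mean()

    def test_mean_within_three_standard_errors(self, wake_only_config):
        cfg = wake_only_config
        _, states = sd.generate_protocol(cfg)
        resp = sd.generate_rc(states, cfg, seed=9)
        n = len(resp)
        rho = cfg.ar_coeff
        se = cfg.rc_sd_awake * np.sqrt((1 + rho) / ((1 - rho) * n))
        assert abs(resp.rc.mean() - cfg.rc_mean_awake) < 3 * se


class TestMissingData:
    def test_zero_fraction_is_identity(self, wake_only_beats):
        out = sd.inject_missing(wake_only_beats, 0.0, seed=0)
        assert np.array_equal(out.beat_times, wake_only_beats.beat_times)
        assert np.array_equal(out.rri, wake_only_beats.rri)

    def test_removed_proportion_near_target(self):
        cfg = sd.SimConfig(missing_fraction=0.0, drift_amplitude_ms=0.0)
        _, states = sd.generate_protocol(cfg, seed=0)
        beats = sd.generate_rri(states, cfg, seed=1)
        total = np.sum(beats.rri)
        out = sd.inject_missing(beats, 0.15, seed=2)
        removed = 1.0 - np.sum(out.rri) / total
        assert 0.14 <= removed <= 0.16

    def test_segments_internally_consistent(self, short_recording):
        beats = short_recording.beats
        beats.validate()
        for seg in beats.segments():
            t, r = beats.beat_times[seg], beats.rri[seg]
            assert np.allclose(np.diff(t), r[:-1] / 1000.0, atol=1e-9)

    def test_gap_mask_flags_flank_every_gap(self, short_recording):
        beats = short_recording.beats
        dt = np.diff(beats.beat_times)
        jumps = np.nonzero(np.abs(beats.rri[:-1] / 1000.0 - dt) > 1e-6)[0]
        assert len(jumps) > 0
        for i in jumps:
            assert beats.gap_mask[i] and beats.gap_mask[i + 1]


def test_seed_determinism_bit_identical():
    cfg = sd.profile_config("S08", duration_h=4.0, seed=11)
    a = sd.simulate_recording(cfg)
    b = sd.simulate_recording(cfg)
    assert np.array_equal(a.beats.beat_times, b.beats.beat_times)
    assert np.array_equal(a.beats.rri, b.beats.rri)
    assert np.array_equal(a.resp.rc, b.resp.rc)
    assert np.array_equal(a.states.state, b.states.state)
    assert np.array_equal(a.events.time_s, b.events.time_s)


def test_csv_round_trip(tmp_path, short_recording):
    rec = short_recording
    rec.write_csvs(tmp_path)
    beats = sd.BeatSeries.read_csv(tmp_path / "beats.csv")
    assert np.allclose(beats.rri, rec.beats.rri)
    assert np.array_equal(beats.gap_mask, rec.beats.gap_mask)
    events = sd.EventLog.read_csv(tmp_path / "events.csv")
    assert list(events.event) == list(rec.events.event)
    states = sd.StateSequence.read_csv(tmp_path / "states.csv")
    assert list(states.state) == list(rec.states.state)
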