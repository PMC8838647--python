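import numpy as np
import pytest

from infantsleep.signals import (
    BreathCycle,
    ChannelSet,
    MovementBurst,
    RegularityCall,
    SignalConfig,
    detect_breath_cycles,
    detect_movement_bursts,
    epoch_features,
    extract_features,
    movement_noise_fraction,
    regularity,
)

FS = 50.0


def sinusoid(freq_hz, duration_s, fs=FS, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t)


def cycles_with_rates(rates_cpm):
    """Back-to-back cycles whose extrapolated rates are exactly as given."""
    t, out = 0.0, []
    for r in rates_cpm:
        d = 60.0 / r
        out.append(BreathCycle(onset_s=t, duration_s=d))
        t += d
    return out


class TestBreathCycles:
    def test_pure_sinusoid_period(self):
        cycles = detect_breath_cycles(sinusoid(0.5, 30.0), FS)
        assert 13 <= len(cycles) <= 15
        assert np.allclose([c.duration_s for c in cycles], 2.0, atol=0.1)

    def test_flat_signal_yields_nothing(self):
        assert detect_breath_cycles(np.zeros(int(30 * FS)), FS) == []
        assert detect_breath_cycles(np.full(int(30 * FS), 3.7), FS) == []

    def test_frequency_step_recovered(self):
        # 0.5 Hz then 1.0 Hz: durations cluster at 2 s then 1 s
        x = np.concatenate([sinusoid(0.5, 15.0), sinusoid(1.0, 15.0)])
        cycles = detect_breath_cycles(x, FS)
        early = [c.duration_s for c in cycles if c.onset_s < 12.0]
        late = [c.duration_s for c in cycles if c.onset_s > 17.0]
        assert np.allclose(early, 2.0, atol=0.15)
        assert np.allclose(late, 1.0, atol=0.15)

    @pytest.mark.parametrize("freq", [0.3, 0.5, 1.0])
    def test_mean_rate_within_5pct(self, freq):
        cycles = detect_breath_cycles(sinusoid(freq, 60.0), FS)
        mean_rate = np.mean([c.rate_cpm for c in cycles])
        assert abs(mean_rate - 60 * freq) / (60 * freq) < 0.05


class TestRegularity:
    def test_zero_variation_regular(self):
        call = regularity(cycles_with_rates([30.0] * 15), (0.0, 30.0))
        assert call.verdict == RegularityCall.REGULAR
        assert call.rate_range_cpm == 0.0

    def test_alternating_durations_irregular(self):
        # durations 1 s and 2 s -> rates 60 and 30 cpm, range 30 >= 20
        cycles = cycles_with_rates([60.0, 30.0] * 5)
        call = regularity(cycles, (0.0, 30.0))
        assert call.verdict == RegularityCall.IRREGULAR
        assert call.rate_range_cpm == pytest.approx(30.0)

    def test_too_few_cycles_undetermined(self):
        call = regularity(cycles_with_rates([30.0] * 3), (0.0, 30.0))
        assert call.verdict == RegularityCall.UNDETERMINED
        assert call.rate_range_cpm is None

    def test_tie_at_threshold_is_irregular(self):
        call = regularity(cycles_with_rates([30.0, 50.0] * 4), (0.0, 60.0))
        assert call.rate_range_cpm == pytest.approx(20.0)
        assert call.verdict == RegularityCall.IRREGULAR

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            regularity([], (10.0, 10.0))

    def test_amplitude_scale_invariance(self, rng):
        x = sinusoid(0.45, 40.0) + 0.05 * rng.normal(size=int(40 * FS))
        base = regularity(detect_breath_cycles(x, FS), (0.0, 30.0))
        for scale in (0.01, 3.0, 250.0):
            scaled = regularity(detect_breath_cycles(scale * x, FS), (0.0, 30.0))
            assert scaled.verdict == base.verdict


class TestMovementBursts:
    def make_pulses(self, pulses, duration_s=30.0, fs=FS, noise=0.01, seed=7):
        rng = np.random.default_rng(seed)
        x = noise * rng.normal(size=int(duration_s * fs))
        for onset, dur, amp in pulses:
            i0, i1 = int(onset * fs), int((onset + dur) * fs)
            x[i0:i1] += amp
        return x

    def test_quiet_signal_no_bursts(self):
        assert detect_movement_bursts(np.zeros(int(30 * FS)), FS) == []

    def test_single_short_pulse_is_twitch(self):
        x = self.make_pulses([(10.0, 0.3, 1.0)])
        bursts = detect_movement_bursts(x, FS)
        assert len(bursts) == 1
        assert bursts[0].kind == "twitch"
        assert bursts[0].onset_s == pytest.approx(10.0, abs=0.3)

    def test_close_pulses_merge(self):
        x = self.make_pulses([(10.0, 0.3, 1.0), (10.8, 0.3, 1.0)])
        bursts = detect_movement_bursts(x, FS)
        assert len(bursts) == 1

    def test_twitch_vs_gross_classification(self):
        x = self.make_pulses([(5.0, 3.0, 2.0), (15.0, 0.2, 0.3), (22.0, 3.0, 2.0)])
        kinds = {round(b.onset_s): b.kind for b in detect_movement_bursts(x, FS)}
        assert kinds[5] == "gross" and kinds[22] == "gross"
        assert kinds[15] == "twitch"


class TestNoiseFraction:
    def test_no_bursts(self):
        assert movement_noise_fraction([], (0.0, 30.0)) == 0.0

    def test_half_covered(self):
        b = MovementBurst(5.0, 15.0, 1.0, "gross")
        assert movement_noise_fraction([b], (0.0, 30.0)) == pytest.approx(0.5)

    def test_overlap_capped_at_one(self):
        bursts = [
            MovementBurst(0.0, 30.0, 1.0, "gross"),
            MovementBurst(10.0, 30.0, 1.0, "gross"),
        ]
        assert movement_noise_fraction(bursts, (0.0, 30.0)) == 1.0


def make_channels(resp, move=None, eyes=None, cry=None, fs=FS, duration_s=60.0):
    n = int(duration_s * fs)
    n_sec = int(duration_s)
    return ChannelSet(
        respiration=resp,
        resp_sample_rate_hz=fs,
        movement=move if move is not None else np.zeros(n),
        move_sample_rate_hz=fs,
        audio_env=np.zeros(n),
        audio_sample_rate_hz=fs,
        eyes_open=eyes if eyes is not None else np.zeros(n_sec, dtype=np.int8),
        cry=cry if cry is not None else np.zeros(n_sec, dtype=np.int8),
        duration_s=duration_s,
    )


class TestEpochFeatures:
    def test_quiet_epoch_profile(self):
        cs = make_channels(sinusoid(0.55, 60.0))
        f = extract_features(cs)[0]
        assert f.resp_regularity.verdict == RegularityCall.REGULAR
        assert f.burst_count == 0
        assert f.eyes_open_fraction == 0.0
        assert f.cry_fraction == 0.0

    def test_burst_covered_epoch_suppresses_respiration(self, rng):
        move = np.zeros(int(60 * FS))
        move[: int(30 * FS)] = 2.0 + 0.1 * rng.normal(size=int(30 * FS))
        cs = make_channels(sinusoid(0.5, 60.0), move=move)
        f = extract_features(cs)[0]
        assert f.movement_noise_fraction > 0.95
        assert f.resp_regularity.verdict == RegularityCall.UNDETERMINED

    def test_all_unknown_eyes_absent(self):
        eyes = np.full(60, -1, dtype=np.int8)
        cs = make_channels(sinusoid(0.5, 60.0), eyes=eyes)
        f = extract_features(cs)[0]
        assert f.eyes_open_fraction is None

    def test_eyes_majority_fraction(self):
        eyes = np.zeros(60, dtype=np.int8)
        eyes[:20] = 1  # 20 s open, 40 s closed in epoch 0
        cs = make_channels(sinusoid(0.5, 60.0), eyes=eyes)
        f = extract_features(cs)[0]
        assert f.eyes_open_fraction == pytest.approx(20 / 30)

    def test_epoch_outside_recording_rejected(self):
        cs = make_channels(sinusoid(0.5, 60.0))
        with pytest.raises(ValueError):
            epoch_features(cs, 5)

    def test_simulator_quiet_epoch_matches_ground_truth(self):
        from infantsleep.simulate import SimConfig, movement_free, simulate_nap
        from infantsleep.core import BehavioralState

        sim = simulate_nap(movement_free(SimConfig(seed=42)))
        feats = extract_features(sim.channels)
        qs = [i for i, lab in enumerate(sim.truth.labels)
              if lab is BehavioralState.QS][:5]
        assert qs, "expected some QS epochs in the simulated nap"
        for i in qs:
            f = feats[i]
            assert f.resp_regularity.verdict == RegularityCall.REGULAR
            assert f.burst_count == 0
            assert f.eyes_open_fraction is None or f.eyes_open_fraction < 0.2
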