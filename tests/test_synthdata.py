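"""Ground-truthed generator: determinism, envelope statistics, modality content."""

import numpy as np
import pytest

from cabum.preprocess import PreprocConfig, condition_recording
from cabum.synthdata import (
    SynthConfig,
    simulate_acoustic,
    simulate_biopotential,
    simulate_envelope,
    simulate_references,
    simulate_session,
)


class TestEnvelope:
    def test_rate_zero_flat(self):
        cfg = SynthConfig(duration_s=600.0, n_contractions=None, contraction_rate_per_10min=0.0)
        env, truth = simulate_envelope(cfg)
        assert np.allclose(env, 0.0)
        assert len(truth.intervals) == 0

    def test_forced_bumps_centered_at_event_times(self):
        cfg = SynthConfig(duration_s=1200.0, n_contractions=None, event_times_s=(300.0, 900.0))
        env, truth = simulate_envelope(cfg)
        assert len(truth.intervals) == 2
        for (onset, offset, peak_t, _), expect in zip(truth.intervals, (300.0, 900.0)):
            assert peak_t == expect
            assert onset < expect < offset

    def test_poisson_mode_count_statistics_match_sampling_oracle(self):
        """Counts follow a min-separation-thinned Poisson process."""
        cfg_kw = dict(duration_s=1800.0, n_contractions=None, contraction_rate_per_10min=4.0)
        counts = [
            len(simulate_envelope(SynthConfig(seed=s, **cfg_kw))[1].intervals)
            for s in range(60)
        ]
        # independent oracle: direct simulation of the same renewal process
        rng = np.random.default_rng(999)
        margin = 75.0
        lo, hi = margin, 1800.0 - margin
        oracle = []
        for _ in range(400):
            t, n = lo, 0
            last = None
            while True:
                t += rng.exponential(150.0)
                if t >= hi:
                    break
                if last is None or t - last >= 150.0:
                    n += 1
                    last = t
            oracle.append(n)
        assert abs(np.mean(counts) - np.mean(oracle)) < 1.0
        assert min(counts) >= min(oracle) - 2 and max(counts) <= max(oracle) + 2

    def test_envelope_nonnegative_and_intervals_cover_bumps(self):
        cfg = SynthConfig(duration_s=1800.0, seed=4)
        env, truth = simulate_envelope(cfg)
        assert env.min() >= 0.0
        for onset, offset, peak_t, _ in truth.intervals:
            i = int(peak_t * 4)
            assert env[i] > 0.1


class TestBiopotential:
    def test_zero_depth_flat_beat_amplitudes(self):
        cfg = SynthConfig(duration_s=300.0, n_contractions=0, modulation_depth=0.0, seed=1)
        env, _ = simulate_envelope(cfg)
        _, _, amps = simulate_biopotential(env, cfg)
        cv = np.std(amps[0]) / np.abs(np.mean(amps[0]))
        assert cv < 0.02

    def test_recovered_amplitudes_regress_on_envelope(self):
        cfg = SynthConfig(duration_s=900.0, event_times_s=(200.0, 500.0, 750.0),
                          n_contractions=None, seed=2)
        env, _ = simulate_envelope(cfg)
        _, beats, amps = simulate_biopotential(env, cfg)
        e = np.interp(beats, np.arange(env.size) / 4.0, env)
        slope, intercept = np.polyfit(e, amps[0], 1)
        pred = slope * e + intercept
        ss_res = np.sum((amps[0] - pred) ** 2)
        ss_tot = np.sum((amps[0] - amps[0].mean()) ** 2)
        assert slope > 0
        assert 1 - ss_res / ss_tot > 0.9

    def test_inverted_channel_has_negative_amplitudes(self):
        cfg = SynthConfig(duration_s=120.0, n_contractions=0, seed=3)
        env, _ = simulate_envelope(cfg)
        _, _, amps = simulate_biopotential(env, cfg)
        for c in cfg.bio_inverted:
            assert np.all(amps[c] < 0)


class TestAcoustic:
    def test_burst_spectral_mass_in_band(self):
        cfg = SynthConfig(duration_s=120.0, n_contractions=0, acu_noise=0.0, seed=4)
        env, _ = simulate_envelope(cfg)
        acu, _, _ = simulate_acoustic(env, cfg)
        spec = np.abs(np.fft.rfft(acu[0])) ** 2
        freqs = np.fft.rfftfreq(acu.shape[1], 1 / 250.0)
        band = (freqs >= 10) & (freqs <= 50)
        assert spec[band].sum() / spec[1:].sum() >= 0.9

    def test_s1_s2_spacing_from_autocorrelation(self):
        cfg = SynthConfig(duration_s=60.0, n_contractions=0, acu_noise=0.0,
                          hr_jitter=0.0, seed=5)
        env, _ = simulate_envelope(cfg)
        acu, _, _ = simulate_acoustic(env, cfg)
        e = np.abs(acu[0])
        e = np.convolve(e, np.ones(13) / 13, mode="same")
        ac = np.correlate(e - e.mean(), e - e.mean(), "full")[e.size - 1 :]
        lo, hi = int(0.2 * 250), int(0.4 * 250)
        lag = (lo + np.argmax(ac[lo:hi])) / 250.0
        assert lag == pytest.approx(0.3, abs=0.04)

    def test_zero_depth_flat_amplitudes(self):
        cfg = SynthConfig(duration_s=120.0, n_contractions=0, modulation_depth=0.0, seed=6)
        env, _ = simulate_envelope(cfg)
        _, _, amps = simulate_acoustic(env, cfg)
        assert np.std(amps[0]) / np.mean(amps[0]) < 0.02


class TestReferences:
    def test_zero_miss_probability_keeps_all(self):
        cfg = SynthConfig(duration_s=1800.0, seed=7, toco_miss_prob=0.0)
        env, truth = simulate_envelope(cfg)
        _, _, toco_ann = simulate_references(env, truth, cfg)
        assert len(toco_ann) == len(truth.intervals)

    def test_miss_probability_bernoulli_fraction(self):
        kept = total = 0
        for s in range(25):
            cfg = SynthConfig(duration_s=1800.0, seed=s, toco_miss_prob=0.6)
            env, truth = simulate_envelope(cfg)
            _, _, toco_ann = simulate_references(env, truth, cfg)
            kept += len(toco_ann)
            total += len(truth.intervals)
        frac = kept / total
        se = np.sqrt(0.4 * 0.6 / total)
        assert abs(frac - 0.4) < 4 * se

    def test_iupc_peaks_track_envelope(self):
        cfg = SynthConfig(duration_s=1800.0, seed=8, iupc_noise_mmhg=0.0)
        env, truth = simulate_envelope(cfg)
        iupc, _, _ = simulate_references(env, truth, cfg)
        for onset, offset, peak_t, amp in truth.intervals:
            i = int(peak_t * 4)
            expect = cfg.iupc_baseline_mmhg + cfg.iupc_scale_mmhg * env[i]
            assert iupc.values[i] == pytest.approx(expect, rel=0.05)


class TestArtifactsAndDeterminism:
    def test_empty_schedule_leaves_channels_unchanged(self):
        cfg = SynthConfig(duration_s=60.0, n_contractions=0, seed=9)
        rec, *_ = simulate_session(cfg)
        rec2, *_ = simulate_session(cfg)
        assert np.array_equal(rec.biopotential, rec2.biopotential)

    def test_artifact_interval_raises_motion_rms(self):
        cfg = SynthConfig(duration_s=120.0, n_contractions=0, seed=10,
                          artifact_intervals_s=((40.0, 50.0),))
        rec, truth, *_ = simulate_session(cfg)
        acc = rec.motion[:3] - rec.motion[:3].mean(axis=1, keepdims=True)
        mag = np.sqrt((acc**2).sum(axis=0))
        per_s = mag.reshape(120, 50)
        rms = np.sqrt((per_s**2).mean(axis=1))
        baseline = np.median(rms)
        assert rms[40:50].min() > 5 * baseline

    def test_dropout_channel_rejected_by_integrity_check(self):
        cfg = SynthConfig(duration_s=120.0, n_contractions=0, seed=11,
                          dropout=(("biopotential", 1, 0.0, 120.0),))
        rec, *_ = simulate_session(cfg)
        with pytest.warns(UserWarning):
            chs = condition_recording(rec, PreprocConfig())
        assert not chs.channels[1].keep
        assert chs.channels[0].keep

    def test_full_determinism_bit_identical(self):
        cfg = SynthConfig(duration_s=90.0, n_contractions=0, seed=12)
        a = simulate_session(cfg)
        b = simulate_session(cfg)
        assert np.array_equal(a[0].biopotential, b[0].biopotential)
        assert np.array_equal(a[0].acoustic, b[0].acoustic)
        assert np.array_equal(a[0].motion, b[0].motion)
        assert np.array_equal(a[2].values, b[2].values)

    def test_modulation_depth_validated(self):
        with pytest.raises(ValueError):
            SynthConfig(modulation_depth=1.5)
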