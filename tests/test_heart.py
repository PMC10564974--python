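"""Interbeat-interval pipeline on synthetic aggregate recordings."""
import numpy as np
import pytest

from dtews.ews import DetrendSpec, compute_ews
from dtews.heart import (
    SAMPLE_RATE,
    SynthConfig,
    bandpass,
    compute_ibis,
    detect_beats,
    detect_pd_onset,
    extract_null_segments,
    synthesize_aggregate_recording,
)


def _sine(freq, seconds=60.0, fs=SAMPLE_RATE):
    t = np.arange(0, seconds, 1 / fs)
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_preserves_a_1hz_tone(self):
        # amplitude from RMS over the middle, away from edge transients
        out = bandpass(_sine(1.0, seconds=120.0))
        mid = out[1200:-1200]
        amplitude = np.sqrt(2) * np.sqrt(np.mean(mid**2))
        assert amplitude == pytest.approx(1.0, rel=0.05)

    def test_dc_offset_is_removed(self):
        out = bandpass(_sine(1.0) + 5.0)
        assert abs(np.mean(out)) < 0.05

    def test_stopband_attenuates_10hz(self):
        out = bandpass(_sine(10.0))
        assert np.max(np.abs(out[200:-200])) < 0.2  # >80% attenuation

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.ones(30))


class TestDetectBeats:
    def test_counts_beats_of_a_1hz_tone(self):
        beats = detect_beats(_sine(1.0, seconds=60.0))
        assert 59 <= len(beats) <= 61
        ibi = compute_ibis(beats)
        assert np.allclose(ibi, 1.0, atol=1 / SAMPLE_RATE)

    def test_constant_signal_has_no_beats(self):
        assert len(detect_beats(np.full(1000, 2.0))) == 0

    def test_gap_straddling_intervals_are_dropped(self):
        beats = np.array([0.0, 1.0, 2.0, 62.0, 63.0])  # 60 s recording pause
        ibi = compute_ibis(beats, gaps=[(2.5, 61.5)])
        assert np.allclose(ibi, [1.0, 1.0, 1.0])


class TestPdOnset:
    def test_constant_ibis_give_no_onset(self):
        assert detect_pd_onset(np.full(100, 1.0)) is None

    def test_perfect_alternans_onset_is_recovered(self):
        ibi = np.full(300, 1.0)
        ibi[200::2] = 0.9
        ibi[201::2] = 1.1
        onset = detect_pd_onset(ibi, window_size=10)
        assert onset is not None
        assert 200 <= onset <= 210

    def test_brief_alternans_fails_persistence(self):
        ibi = np.full(100, 1.0)
        ibi[50:55:2] = 0.9
        ibi[51:56:2] = 1.1
        assert detect_pd_onset(ibi) is None

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            detect_pd_onset(np.ones(15))


class TestNullSegments:
    def test_requested_number_and_length_range(self, rng):
        records = [rng.normal(1.0, 0.05, n) for n in (600, 800, 1000)]
        segs = extract_null_segments(records, 23, rng_seed=4)
        assert len(segs) == 23
        assert all(100 <= len(s) <= 500 for s in segs)

    def test_minimum_length_record_is_used_whole(self, rng):
        segs = extract_null_segments([rng.normal(1.0, 0.05, 100)], 5, rng_seed=1)
        assert all(len(s) == 100 for s in segs)

    def test_short_records_are_skipped_with_warning(self, rng):
        with pytest.warns(UserWarning):
            segs = extract_null_segments(
                [rng.normal(1, 0.05, 50), rng.normal(1, 0.05, 300)], 3, rng_seed=2
            )
        assert len(segs) == 3

    def test_seeded_reproducibility(self, rng):
        records = [rng.normal(1.0, 0.05, 700)]
        a = extract_null_segments(records, 4, rng_seed=9)
        b = extract_null_segments(records, 4, rng_seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestSynthesis:
    def test_noise_free_constant_ibis_are_recovered_at_sample_resolution(self):
        cfg = SynthConfig(
            n_beats=120, drift_amplitude=0.0, noise_sd=0.0, trace_noise_sd=0.0
        )
        trace, truth = synthesize_aggregate_recording(cfg, rng_seed=0)
        ibi = compute_ibis(detect_beats(bandpass(trace)))
        assert len(ibi) == pytest.approx(len(truth.ibi), abs=2)
        assert np.allclose(ibi, 1.0, atol=1 / SAMPLE_RATE)

    def test_end_to_end_onset_recovery_single_seed(self):
        cfg = SynthConfig(n_beats=300, alternans_onset=230)
        trace, _ = synthesize_aggregate_recording(cfg, rng_seed=3)
        ibi = compute_ibis(detect_beats(bandpass(trace)))
        onset = detect_pd_onset(ibi)
        assert onset is not None
        assert abs(onset - 230) <= 10

    def test_no_onset_configured_gives_no_detection(self):
        hits = 0
        for seed in range(20):
            cfg = SynthConfig(n_beats=300, alternans_onset=None)
            trace, _ = synthesize_aggregate_recording(cfg, rng_seed=seed)
            ibi = compute_ibis(detect_beats(bandpass(trace)))
            if detect_pd_onset(ibi) is not None:
                hits += 1
        assert hits <= 2

    def test_gradual_alternans_shows_the_period_doubling_ews_pattern(self):
        """Growing alternans raises variance and drives lag-1
        autocorrelation down (theta = pi direction) in the majority of
        seeded records, using the Gaussian bandwidth-20 detrend."""
        up_var = down_ac = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SynthConfig(
                n_beats=300,
                alternans_onset=150,
                alternans_initial=0.005,
                alternans_growth=1.04,
                alternans_max=0.10,
            )
            _, truth = synthesize_aggregate_recording(cfg, rng_seed=seed)
            seg = truth.ibi[:260]
            res = compute_ews(seg, DetrendSpec(method="gaussian", bandwidth=20), 0.5)
            up_var += res.tau_variance > 0
            down_ac += res.tau_ac1 < 0
        assert up_var > n_seeds / 2
        assert down_ac > n_seeds / 2
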