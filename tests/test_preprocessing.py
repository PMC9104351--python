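"""Preprocessing pipeline: resampling, segmentation arithmetic, min-max
normalization laws, and AWGN power calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beatformer import (EcgRecord, NoiseSpec, add_awgn, minmax_normalize,
                        preprocess, resample_record, segment_heartbeats)


def _sine_record(fs=128, seconds=1000, freq=5.0):
    t = np.arange(int(fs * seconds)) / fs
    x = np.sin(2 * np.pi * freq * t)
    peaks = np.arange(fs, x.size - fs, fs)
    return EcgRecord("sine", "normal", fs, x, peaks)


class TestResample:
    def test_128hz_to_250hz_length(self):
        rec = EcgRecord("s", "normal", 128, np.random.default_rng(0).random(128_000),
                        [64_000])
        out = resample_record(rec, 250)
        assert out.fs == 250
        assert out.samples.size == 250_000

    def test_identity_when_rate_matches(self, small_cohort):
        rec = small_cohort[0]
        out = resample_record(rec, rec.fs)
        np.testing.assert_array_equal(out.samples, rec.samples)
        np.testing.assert_array_equal(out.r_peaks, rec.r_peaks)

    def test_sinusoid_amplitude_preserved(self):
        """A band-limited tone survives anti-aliased resampling to <1% RMS."""
        rec = _sine_record(fs=128, seconds=100, freq=5.0)
        out = resample_record(rec, 250, snap_r_peaks=False)
        t = np.arange(out.samples.size) / 250
        ideal = np.sin(2 * np.pi * 5.0 * t)
        core = slice(1000, -1000)  # ignore filter edge effects
        rms_err = np.sqrt(np.mean((out.samples[core] - ideal[core]) ** 2))
        assert rms_err < 0.01 * np.sqrt(0.5)

    def test_r_peaks_rescaled(self):
        rec = _sine_record(fs=128, seconds=50)
        out = resample_record(rec, 250, snap_r_peaks=False)
        expected = np.round(rec.r_peaks * 250 / 128).astype(int)
        np.testing.assert_array_equal(out.r_peaks, expected)


class TestSegmentation:
    def test_window_index_arithmetic(self):
        """At 250 Hz an R peak at 1000 yields the half-open window
        [900, 1150) of exactly 250 samples."""
        x = np.zeros(2000)
        x[900:1150] = np.linspace(0, 1, 250)  # non-flat content
        rec = EcgRecord("s", "normal", 250, x, [1000])
        segs, skipped = segment_heartbeats(rec, normalize=False)
        assert skipped == 0
        assert len(segs) == 1
        assert segs[0].values.size == 250
        np.testing.assert_array_equal(segs[0].values, x[900:1150])

    def test_boundary_peak_skipped(self):
        rec = EcgRecord("s", "normal", 250,
                        np.random.default_rng(0).random(500), [50])
        segs, skipped = segment_heartbeats(rec)
        assert (len(segs), skipped) == (0, 1)

    def test_count_conservation(self, small_cohort):
        """Segments + skips always equals the number of annotations."""
        for rec in small_cohort:
            segs, skipped = segment_heartbeats(rec)
            assert len(segs) + skipped == rec.r_peaks.size


class TestMinMaxNormalize:
    @pytest.mark.parametrize("values,expected", [
        ([2, 4, 6], [0, 0.5, 1]),
        ([-1, 0, 3], [0, 0.25, 1]),
    ])
    def test_affine_map(self, values, expected):
        np.testing.assert_allclose(minmax_normalize(values), expected)

    def test_flat_segment_rejected(self):
        with pytest.raises(ValueError, match="flat segment"):
            minmax_normalize(np.ones(250))

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50),
           st.floats(0.1, 100.0), st.floats(-100.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_affine_invariant(self, values, scale, shift):
        x = np.asarray(values)
        if x.max() - x.min() < 1e-6:
            return
        base = minmax_normalize(x)
        np.testing.assert_allclose(minmax_normalize(base), base, atol=1e-12)
        np.testing.assert_allclose(minmax_normalize(x * scale + shift), base,
                                   atol=1e-6)


class TestAwgn:
    def test_infinite_snr_is_identity(self, rng):
        x = rng.random(1000)
        out = add_awgn(x, NoiseSpec(snr_db=math.inf, rng_seed=0))
        np.testing.assert_array_equal(out, x)

    def test_empirical_snr_within_band(self, rng):
        """Measured power ratio lands within 0.3 dB of the requested SNR."""
        x = np.sin(np.linspace(0, 400 * np.pi, 25_000))
        noisy = add_awgn(x, NoiseSpec(snr_db=12.0, rng_seed=3))
        noise = noisy - x
        snr = 10 * np.log10(np.mean(x ** 2) / np.mean(noise ** 2))
        assert abs(snr - 12.0) < 0.3

    def test_seeded_determinism(self, rng):
        x = rng.random(500)
        a = add_awgn(x, NoiseSpec(snr_db=6.0, rng_seed=9))
        b = add_awgn(x, NoiseSpec(snr_db=6.0, rng_seed=9))
        np.testing.assert_array_equal(a, b)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError, match="zero-power"):
            add_awgn(np.zeros(100), NoiseSpec(snr_db=12.0))

    def test_lower_snr_means_larger_perturbation(self, rng):
        x = rng.standard_normal(20_000)
        mse = [np.mean((add_awgn(x, NoiseSpec(snr_db=s, rng_seed=1)) - x) ** 2)
               for s in (24.0, 12.0, 6.0)]
        assert mse[0] < mse[1] < mse[2]


class TestPipeline:
    def test_all_segments_normalized_and_sized(self, small_segments):
        assert len(small_segments) > 0
        for seg in small_segments[::17]:
            assert seg.values.size == 250
            assert seg.values.min() == pytest.approx(0.0, abs=1e-12)
            assert seg.values.max() == pytest.approx(1.0, abs=1e-12)

    def test_segment_count(self, small_cohort, small_spec, small_segments):
        assert len(small_segments) == (len(small_cohort)
                                       * small_spec.beats_per_subject)

    def test_infinite_noise_equals_no_noise(self, small_cohort):
        clean = preprocess(small_cohort, noise=None)
        inf = preprocess(small_cohort, noise=NoiseSpec(snr_db=math.inf))
        for a, b in zip(clean, inf):
            np.testing.assert_array_equal(a.values, b.values)
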