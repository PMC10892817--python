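"""Filter analytics, despiking, standardization, and segmentation."""

import numpy as np
import pytest

from osadetect.ecg_io import EcgRecord
from osadetect.errors import ValidationError
from osadetect.preprocess import (EcgSegment, FilterSpec, PreprocessConfig,
                                  bandlimit, despike_median, preprocess_record,
                                  resample_linear, segment_minutes, zscore)

LOWPASS = FilterSpec("lowpass", 4, 40.0)
BANDPASS = FilterSpec("bandpass", 4, (0.5, 15.0))


def steady_amplitude(y, fs, f, discard_s=2.0):
    """Amplitude of a filtered sinusoid by quadrature demodulation,
    edges discarded."""
    k = int(discard_s * fs)
    core = y[k:len(y) - k]
    # trim to an integer number of cycles so the projection is unbiased
    n_cyc = int(np.floor(len(core) * f / fs))
    n = int(round(n_cyc * fs / f))
    t = np.arange(n) / fs
    z = core[:n] * np.exp(-2j * np.pi * f * t)
    return 2.0 * np.abs(z.mean())


def lowpass_filtfilt_gain(f, fc, fs, order=4):
    """Analytic forward-backward gain of the digital Butterworth low-pass:
    |H|^2 with the bilinear-transform frequency prewarp."""
    v, vc = np.tan(np.pi * f / fs), np.tan(np.pi * fc / fs)
    return 1.0 / (1.0 + (v / vc) ** (2 * order))


def bandpass_filtfilt_gain(f, fl, fh, fs, order=4):
    v = np.tan(np.pi * f / fs)
    vl, vh = np.tan(np.pi * fl / fs), np.tan(np.pi * fh / fs)
    u = (v * v - vl * vh) / (v * (vh - vl))
    return 1.0 / (1.0 + u ** (2 * order))


class TestBandlimit:
    def test_dc_blocked_by_bandpass(self):
        x = np.ones(2000)
        y = bandlimit(x, 100.0, BANDPASS)
        assert np.abs(y[500:1500]).max() < 1e-3

    def test_lowpass_stopband_matches_butterworth_magnitude(self):
        # 60 Hz probe against the order-4 digital design at fc=40, fs=200
        fs, f = 200.0, 60.0
        t = np.arange(int(20 * fs)) / fs
        y = bandlimit(np.sin(2 * np.pi * f * t), fs, LOWPASS)
        expected = lowpass_filtfilt_gain(f, 40.0, fs)
        assert steady_amplitude(y, fs, f) == pytest.approx(expected, rel=0.05)

    def test_bandpass_passband_gain_near_unity(self):
        fs, f = 100.0, 5.0
        t = np.arange(int(30 * fs)) / fs
        y = bandlimit(np.sin(2 * np.pi * f * t), fs, BANDPASS)
        amp = steady_amplitude(y, fs, f, discard_s=5.0)
        assert 0.95 <= amp <= 1.0

    @pytest.mark.parametrize("f_probe", [10.0, 20.0, 40.0, 60.0, 80.0])
    def test_lowpass_attenuation_analytic(self, f_probe):
        fs, fc = 250.0, 40.0
        t = np.arange(int(30 * fs)) / fs
        spec = FilterSpec("lowpass", 4, fc)
        y = bandlimit(np.sin(2 * np.pi * f_probe * t), fs, spec)
        expected = lowpass_filtfilt_gain(f_probe, fc, fs)
        assert steady_amplitude(y, fs, f_probe, 5.0) == pytest.approx(
            expected, rel=0.05)

    @pytest.mark.parametrize("f_probe", [1.0, 3.0, 5.0, 10.0, 20.0])
    def test_bandpass_attenuation_analytic(self, f_probe):
        fs = 100.0
        t = np.arange(int(40 * fs)) / fs
        y = bandlimit(np.sin(2 * np.pi * f_probe * t), fs, BANDPASS)
        expected = bandpass_filtfilt_gain(f_probe, 0.5, 15.0, fs)
        assert steady_amplitude(y, fs, f_probe, 8.0) == pytest.approx(
            expected, rel=0.05)

    def test_linearity(self, rng):
        x, y = rng.standard_normal(3000), rng.standard_normal(3000)
        a, b = 2.5, -1.3
        lhs = bandlimit(a * x + b * y, 100.0, BANDPASS)
        rhs = a * bandlimit(x, 100.0, BANDPASS) + b * bandlimit(y, 100.0, BANDPASS)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-8, atol=1e-10)

    def test_zero_phase_pulse_stays_put(self):
        # a smooth in-band pulse should not shift under filtfilt
        fs = 100.0
        t = np.arange(3000) / fs
        x = np.exp(-((t - 15.0) ** 2) / (2 * 0.5 ** 2))
        y = bandlimit(x, fs, FilterSpec("bandpass", 4, (0.05, 10.0)))
        assert abs(int(np.argmax(y)) - int(np.argmax(x))) < 1

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            bandlimit(np.zeros(100), 80.0, LOWPASS)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValidationError):
            bandlimit(np.zeros(10), 100.0, LOWPASS)


class TestDespike:
    def test_isolated_spike_removed(self):
        np.testing.assert_array_equal(
            despike_median(np.array([0.0, 0, 9, 0, 0]), 3), np.zeros(5))

    def test_monotone_ramp_unchanged(self):
        x = np.array([1.0, 2, 3, 4, 5])
        np.testing.assert_array_equal(despike_median(x, 3), x)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError):
            despike_median(np.zeros(10), 4)


class TestZscore:
    def test_two_level_example(self):
        np.testing.assert_allclose(zscore(np.array([0.0, 0, 4, 4])),
                                   [-1, -1, 1, 1])

    def test_standardizes_any_nonconstant_input(self, rng):
        z = zscore(rng.standard_normal(500) * 7 + 3)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std() - 1.0) < 1e-10

    def test_constant_input_warns_and_zeroes(self):
        with pytest.warns(RuntimeWarning):
            z = zscore(np.array([5.0, 5, 5]))
        np.testing.assert_array_equal(z, np.zeros(3))


class TestResample:
    def test_length_and_tone_preserved(self):
        fs_in, fs_out, f = 250.0, 100.0, 2.0
        t = np.arange(int(10 * fs_in)) / fs_in
        y = resample_linear(np.sin(2 * np.pi * f * t), fs_in, fs_out)
        assert len(y) == 1000
        t_out = np.arange(len(y)) / fs_out
        np.testing.assert_allclose(y, np.sin(2 * np.pi * f * t_out), atol=2e-3)

    def test_identity_rate_is_identity(self, rng):
        x = rng.standard_normal(500)
        np.testing.assert_allclose(resample_linear(x, 100.0, 100.0), x)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValidationError):
            resample_linear(np.zeros(10), 0.0, 100.0)


class TestSegmentation:
    def test_segment_geometry_and_labels(self, labeled_record):
        segs = segment_minutes(labeled_record)
        assert [s.label for s in segs] == ["N", "A", "N"]
        assert all(len(s.samples) == 6000 for s in segs)
        assert [s.minute_index for s in segs] == [0, 1, 2]
        recon = np.concatenate([s.samples for s in segs])
        np.testing.assert_array_equal(recon, labeled_record.samples)

    def test_trailing_partial_minute_dropped(self):
        rec = EcgRecord("r", np.arange(9000) / 1000.0, 100.0, labels=["N"])
        segs = segment_minutes(rec)
        assert len(segs) == 1
        np.testing.assert_array_equal(segs[0].samples, rec.samples[:6000])

    def test_count_is_min_of_labels_and_minutes(self):
        rec = EcgRecord("r", np.zeros(18000), 100.0, labels=["N", "A"])
        assert len(segment_minutes(rec)) == 2

    def test_unlabeled_record_rejected(self):
        with pytest.raises(ValidationError):
            segment_minutes(EcgRecord("r", np.zeros(6000), 100.0))

    def test_wrong_segment_length_rejected(self):
        with pytest.raises(ValidationError):
            EcgSegment("r", 0, np.zeros(5999), "N", fs=100.0)


class TestPipeline:
    def test_segments_standardized(self, labeled_record):
        segs = preprocess_record(labeled_record)
        assert len(segs) == 3
        for seg in segs:
            assert abs(seg.samples.mean()) < 1e-10
            assert abs(seg.samples.std() - 1.0) < 1e-10

    def test_all_zero_record_warns(self):
        rec = EcgRecord("z", np.zeros(18000), 100.0, labels=["N"] * 3)
        with pytest.warns(RuntimeWarning):
            segs = preprocess_record(rec)
        for seg in segs:
            np.testing.assert_array_equal(seg.samples, np.zeros(6000))

    def test_deterministic(self, labeled_record):
        a = preprocess_record(labeled_record, PreprocessConfig())
        b = preprocess_record(labeled_record, PreprocessConfig())
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.samples, sb.samples)
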