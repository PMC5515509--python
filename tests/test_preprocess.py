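"""Conditioning chain: filtering, decimation, epoching, rejection,
amplitude normalisation."""

import numpy as np
import pytest
from scipy import signal as sps

from earsleep.errors import DegenerateDataError, InputError
from earsleep.preprocess import (
    PreprocessConfig,
    bandpass_filter,
    downsample,
    normalize_amplitude_range,
    preprocess_for_classification,
    reject_epochs,
    segment_epochs,
)
from earsleep.synthetic import generate_recording, inject_artifacts

FS = 200.0


def sine(freq, fs=FS, duration=30.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    def test_out_of_band_tone_suppressed(self):
        """A 50 Hz tone through (0.5, 30) should drop below 5% RMS.

        The analytic magnitude of the squared (forward-backward) 4th-order
        design at 50 Hz confirms the headroom.
        """
        sos = sps.butter(4, [0.5, 30], btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[50.0], fs=FS)
        assert np.abs(h[0]) ** 2 < 0.05  # analytic oracle, filtfilt response
        x = sine(50.0)
        y = bandpass_filter(x, FS, 0.5, 30.0)
        edge = int(2 * FS)  # the filtfilt start-up transient is not signal
        assert rms(y[edge:-edge]) < 0.05 * rms(x)

    def test_in_band_tone_preserved(self):
        x = sine(10.0)
        y = bandpass_filter(x, FS, 0.5, 30.0)
        edge = int(2 * FS)
        assert rms(y[edge:-edge]) == pytest.approx(rms(x[edge:-edge]), rel=0.05)

    def test_dc_removed(self):
        y = bandpass_filter(np.full(6000, 100.0), FS, 0.5, 30.0)
        assert abs(np.mean(y)) < 1e-6 * 100.0

    def test_single_pass_corners_at_minus_3db(self):
        sos = sps.butter(4, [0.5, 30], btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[0.5, 30.0], fs=FS)
        gains_db = 20 * np.log10(np.abs(h))
        assert np.all(np.abs(gains_db - (-3.0)) < 0.5)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(6000)
        a = 3.7
        lhs = bandpass_filter(a * x, FS, 0.5, 30.0)
        rhs = a * bandpass_filter(x, FS, 0.5, 30.0)
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_corner_at_nyquist_rejected(self):
        with pytest.raises(InputError, match="Nyquist"):
            bandpass_filter(sine(10.0), FS, 0.5, 100.0)


class TestDownsample:
    def test_length_1200_to_200(self):
        out = downsample(np.zeros(3_240_000), 1200.0, 200.0)
        assert out.size == 540_000

    def test_slow_tone_survives(self):
        x = sine(5.0, fs=1200.0)
        y = downsample(x, 1200.0, 200.0)
        edge = int(2 * 200)
        assert rms(y[edge:-edge]) == pytest.approx(rms(x), rel=0.02)

    def test_out_of_band_tone_attenuated_40db(self):
        """A 90 Hz tone must not leak into 0.5-30 Hz above -40 dB."""
        x = sine(90.0, fs=1200.0, duration=30.0)
        y = downsample(x, 1200.0, 200.0)
        in_band = bandpass_filter(y, 200.0, 0.5, 30.0)
        edge = int(2 * 200)
        assert rms(in_band[edge:-edge]) < 1e-2 * rms(x)  # -40 dB in amplitude

    def test_upsampling_rejected(self):
        with pytest.raises(InputError, match="exceeds"):
            downsample(np.zeros(100), 200.0, 400.0)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(InputError, match="integer decimation"):
            downsample(np.zeros(100), 1200.0, 500.0)


class TestSegment:
    def test_ninety_epochs(self):
        es = segment_epochs(np.zeros(540_000), FS, 30.0)
        assert len(es.epochs) == 90
        assert all(ep.samples.size == 6000 for ep in es.epochs)
        assert es.kept_mask.all()

    def test_trailing_partial_window_dropped(self):
        es = segment_epochs(np.zeros(6001), FS, 30.0)
        assert len(es.epochs) == 1

    def test_short_signal_rejected(self):
        with pytest.raises(InputError, match="shorter than one"):
            segment_epochs(np.zeros(5999), FS, 30.0)


class TestReject:
    def test_quiet_epochs_all_kept(self):
        rng = np.random.default_rng(1)
        x = np.clip(30 * rng.standard_normal(60_000), -100, 100)
        es = reject_epochs(segment_epochs(x, FS, 30.0), 400.0)
        assert es.kept_mask.all()

    def test_exact_threshold_kept(self):
        x = np.zeros(6000)
        x[100] = 400.0
        es = reject_epochs(segment_epochs(x, FS, 30.0), 400.0)
        assert es.kept_mask.all()
        x[100] = 400.0000001
        es = reject_epochs(segment_epochs(x, FS, 30.0), 400.0)
        assert not es.kept_mask.any()

    def test_survivors_keep_original_order(self):
        x = np.zeros(6000 * 5)
        x[6000 * 2 + 7] = 999.0
        es = reject_epochs(segment_epochs(x, FS, 30.0), 400.0)
        assert list(es.kept_indices) == [0, 1, 3, 4]
        assert [ep.index for ep in es.epochs] == [0, 1, 3, 4]

    def test_injected_artifacts_rejected_at_injection_indices(self):
        rec, _ = generate_recording(["N1"] * 10, seed=2)
        rec, injected = inject_artifacts(rec, 3, amplitude=500.0, seed=6)
        es = preprocess_for_classification(rec.samples[0], rec.fs)
        assert len(es.epochs) == 7
        assert set(np.flatnonzero(~es.kept_mask)) == set(injected)

    def test_bad_threshold_rejected(self):
        with pytest.raises(InputError, match="threshold"):
            reject_epochs(segment_epochs(np.zeros(6000), FS, 30.0), 0.0)


class TestNormalizeAmplitudeRange:
    def test_identity(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(5000)
        assert np.allclose(normalize_amplitude_range(x, x), x, atol=1e-12)

    def test_recovers_known_scale(self):
        rng = np.random.default_rng(4)
        ref = 40 * rng.standard_normal(5000)
        ear = 0.1 * ref
        out = normalize_amplitude_range(ear, ref)
        scale = np.std(out) / np.std(ear)
        assert scale == pytest.approx(10.0, rel=0.01)

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateDataError, match="zero robust"):
            normalize_amplitude_range(np.full(100, 5.0), np.arange(100.0))


def test_config_validation():
    with pytest.raises(InputError):
        PreprocessConfig(classify_band=(30.0, 0.5))
    with pytest.raises(InputError):
        PreprocessConfig(reject_threshold=-1.0)
    with pytest.raises(InputError):
        PreprocessConfig(reject_stage="sometime")


def test_reject_stage_orders_both_run():
    rec, _ = generate_recording(["N2"] * 3, seed=8)
    pre = preprocess_for_classification(
        rec.samples[0], rec.fs, PreprocessConfig(reject_stage="pre_filter")
    )
    post = preprocess_for_classification(
        rec.samples[0], rec.fs, PreprocessConfig(reject_stage="post_filter")
    )
    # clean data: same survivors either way, filtered output identical
    assert np.array_equal(pre.kept_mask, post.kept_mask)
    assert np.allclose(pre.epochs[0].samples, post.epochs[0].samples)
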