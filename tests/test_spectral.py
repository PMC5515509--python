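"""PSD estimation and spectral-edge-frequency extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earsleep.containers import Epoch
from earsleep.errors import DegenerateDataError, InputError
from earsleep.spectral import (
    BANDS,
    BandDef,
    PSD,
    SEF_FEATURE_NAMES,
    power_spectral_density,
    sef_feature_vector,
    spectral_edge_frequency,
)
from earsleep.synthetic import generate_epoch
from earsleep.preprocess import bandpass_filter, downsample

from .oracles import sef_bruteforce

FS = 200.0


def sine_epoch(freq, amp=20.0, fs=FS, duration=30.0):
    t = np.arange(int(duration * fs)) / fs
    return Epoch(amp * np.sin(2 * np.pi * freq * t), fs=fs)


class TestPsd:
    def test_parseval_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(6000)
        psd = power_spectral_density(x, fs=FS)
        assert psd.resolution == pytest.approx(0.25)
        integral = np.sum(psd.power) * psd.resolution
        assert integral == pytest.approx(float(np.var(x)), rel=0.02)

    def test_white_noise_is_flat_in_coarse_bins(self):
        """Median over 50 seeds of the 2 Hz-binned max/min ratio stays < 3."""
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            psd = power_spectral_density(rng.standard_normal(6000), fs=FS)
            nbin = int(2.0 / psd.resolution)
            usable = (psd.power.size // nbin) * nbin
            binned = psd.power[:usable].reshape(-1, nbin).mean(axis=1)
            ratios.append(binned.max() / binned.min())
        assert np.median(ratios) < 3.0

    def test_pure_tone_concentrates_power(self):
        psd = power_spectral_density(sine_epoch(10.0))
        peak = int(np.argmax(psd.power))
        assert psd.freqs[peak] == pytest.approx(10.0, abs=psd.resolution)
        # Hann leakage confines the tone to the peak bin and its neighbours
        window = slice(max(peak - 1, 0), peak + 2)
        assert np.sum(psd.power[window]) >= 0.9 * np.sum(psd.power)

    def test_zero_signal_flagged(self):
        with pytest.warns(UserWarning, match="constant epoch"):
            psd = power_spectral_density(np.zeros(6000), fs=FS)
        assert not np.any(psd.power > 0)

    def test_too_short_epoch_rejected(self):
        with pytest.raises(InputError, match="too short"):
            power_spectral_density(np.zeros(100), fs=FS)


class TestSpectralEdgeFrequency:
    def test_four_bin_worked_example(self):
        """power [1,2,3,4] on [8,9,10,11] Hz: SEF50=10, SEF95=11, SEFd=1."""
        psd = PSD(np.array([8.0, 9.0, 10.0, 11.0]),
                  np.array([1.0, 2.0, 3.0, 4.0]), resolution=1.0)
        band = BandDef("alpha_low_wide", 8.0, 11.0)
        assert spectral_edge_frequency(psd, band, 50) == 10.0
        assert spectral_edge_frequency(psd, band, 95) == 11.0

    def test_single_loaded_bin(self):
        psd = PSD(np.arange(8.0, 12.0), np.array([0.0, 0.0, 5.0, 0.0]),
                  resolution=1.0)
        band = BandDef("b", 8.0, 11.0)
        assert spectral_edge_frequency(psd, band, 50) == 10.0
        assert spectral_edge_frequency(psd, band, 95) == 10.0

    def test_uniform_spectrum_median_at_band_centre(self):
        freqs = np.arange(0.0, 100.0, 0.25)
        psd = PSD(freqs, np.ones_like(freqs), resolution=0.25)
        band = BandDef("alpha", 8.0, 15.0)
        sef50 = spectral_edge_frequency(psd, band, 50)
        assert abs(sef50 - 11.5) <= 0.25

    def test_zero_band_power_rejected(self):
        freqs = np.arange(0.0, 100.0, 0.25)
        power = np.where(freqs < 16, 1.0, 0.0)
        psd = PSD(freqs, power, resolution=0.25)
        with pytest.raises(DegenerateDataError, match="zero power"):
            spectral_edge_frequency(psd, BandDef("beta", 16.0, 30.0), 50)

    def test_matches_bruteforce_oracle_on_random_spectra(self):
        rng = np.random.default_rng(7)
        freqs = np.arange(0.0, 100.0, 0.25)
        for _ in range(50):
            power = rng.gamma(1.5, 1.0, size=freqs.size)
            psd = PSD(freqs, power, resolution=0.25)
            for band in BANDS:
                for r in (25.0, 50.0, 75.0, 95.0):
                    ours = spectral_edge_frequency(psd, band, r)
                    ref = sef_bruteforce(freqs, power, band.f_low, band.f_high, r)
                    assert ours == ref

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), r1=st.floats(5, 90), dr=st.floats(1, 9))
    def test_monotone_in_r_and_within_band(self, seed, r1, dr):
        rng = np.random.default_rng(seed)
        freqs = np.arange(0.0, 100.0, 0.25)
        psd = PSD(freqs, rng.gamma(1.0, 1.0, size=freqs.size), resolution=0.25)
        band = BANDS[1]  # delta_alpha, 0.5-16 Hz
        lo = spectral_edge_frequency(psd, band, r1)
        hi = spectral_edge_frequency(psd, band, r1 + dr)
        assert band.f_low <= lo <= hi <= band.f_high


class TestSefFeatureVector:
    def test_fifteen_named_values_with_sefd_identity(self):
        feats = sef_feature_vector(sine_epoch(10.0))
        assert tuple(feats) == SEF_FEATURE_NAMES[:15]
        assert len(feats) == 15
        for band in BANDS:
            d = feats[f"{band.name}_SEF95"] - feats[f"{band.name}_SEF50"]
            assert feats[f"{band.name}_SEFd"] == pytest.approx(d, abs=1e-12)
            assert feats[f"{band.name}_SEFd"] >= 0

    def test_scale_invariance(self):
        ep = sine_epoch(10.0)
        rng = np.random.default_rng(1)
        ep.samples += rng.standard_normal(ep.samples.size)
        a = sef_feature_vector(ep)
        b = sef_feature_vector(Epoch(123.4 * ep.samples, fs=ep.fs))
        for name in a:
            assert a[name] == pytest.approx(b[name], abs=1e-9)

    def test_pure_20hz_tone_sets_beta_edge(self):
        feats = sef_feature_vector(sine_epoch(20.0, amp=30.0))
        assert feats["beta_SEF50"] == pytest.approx(20.0, abs=0.25)

    def test_wake_edge_above_deep_sleep_edge(self):
        """The broadband wake spectrum pushes SEF50 far above the
        delta-dominated N3 value in the full 0.5-30 Hz band."""
        for seed in range(5):
            vals = {}
            for stage in ("W", "N3"):
                x = downsample(generate_epoch(stage, seed=seed).samples, 1200, 200)
                x = bandpass_filter(x, 200, 0.5, 30)
                vals[stage] = sef_feature_vector(Epoch(x, fs=200.0))
            assert vals["W"]["delta_beta_SEF50"] > vals["N3"]["delta_beta_SEF50"]

    def test_flat_band_reported_missing(self):
        with pytest.warns(UserWarning, match="zero power"):
            feats = sef_feature_vector(sine_epoch(10.0, amp=0.0))
        assert all(np.isnan(v) for v in feats.values())
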