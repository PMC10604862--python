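"""Epoching, filtering, and differential-entropy extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibceeg.signal_prep import (
    DEFAULT_BANDS,
    BandDefinition,
    EpochedEEG,
    bandpass,
    de_gaussian,
    extract_band_de,
    notch,
    segment_epochs,
)

ALPHA = DEFAULT_BANDS[2]
GAMMA = DEFAULT_BANDS[4]


def _sine(freq, fs, seconds):
    t = np.arange(int(fs * seconds)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestSegmentEpochs:
    @pytest.mark.parametrize(
        "seconds,expected_epochs",
        [(60.0, 12), (12.0, 2), (5.0, 1)],
    )
    def test_epoch_counts(self, seconds, expected_epochs):
        fs = 200.0
        seg = np.random.default_rng(0).standard_normal((3, int(fs * seconds)))
        eeg = segment_epochs([seg], fs, [1], epoch_seconds=5.0)
        assert eeg.n_epochs == expected_epochs
        assert eeg.n_samples == 1000
        assert np.all(eeg.labels == 1)
        assert np.all(eeg.block_ids == 0)

    def test_single_epoch_is_identity(self):
        fs = 200.0
        seg = np.random.default_rng(1).standard_normal((2, 1000))
        eeg = segment_epochs([seg], fs, [0], epoch_seconds=5.0)
        np.testing.assert_array_equal(eeg.data[0], seg)

    def test_trailing_samples_discarded_not_padded(self):
        seg = np.ones((1, 1400))
        eeg = segment_epochs([seg], 200.0, [0], epoch_seconds=5.0)
        assert eeg.n_epochs == 1

    def test_too_short_segment_errors_with_index(self):
        good = np.zeros((1, 1000))
        short = np.zeros((1, 900))
        with pytest.raises(ValueError, match="segment 1"):
            segment_epochs([good, short], 200.0, [0, 1], epoch_seconds=5.0)

    def test_overlap_produces_more_epochs(self):
        seg = np.random.default_rng(2).standard_normal((1, 2000))
        no_ov = segment_epochs([seg], 200.0, [0], epoch_seconds=5.0)
        ov = segment_epochs([seg], 200.0, [0], epoch_seconds=5.0, overlap_seconds=2.5)
        assert ov.n_epochs == 2 * no_ov.n_epochs - 1


class TestFilters:
    def test_in_band_sinusoid_power_preserved(self):
        x = _sine(10.0, 200.0, 10.0)
        y = bandpass(x, 200.0, ALPHA)
        assert y.var() >= 0.9 * x.var()

    def test_out_of_band_sinusoid_rejected(self):
        x = _sine(10.0, 200.0, 10.0)
        y = bandpass(x, 200.0, GAMMA)
        assert y.var() <= 0.01 * x.var()

    def test_zero_signal_maps_to_zero(self):
        assert np.allclose(bandpass(np.zeros(1000), 200.0, ALPHA), 0.0)
        assert np.allclose(notch(np.zeros(1000), 200.0, 50.0), 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(100), 80.0, GAMMA)

    def test_notch_attenuates_mains(self):
        x = _sine(50.0, 200.0, 10.0)
        assert notch(x, 200.0, 50.0).var() <= 0.05 * x.var()

    def test_notch_preserves_distant_frequency(self):
        x = _sine(10.0, 200.0, 10.0)
        assert abs(notch(x, 200.0, 50.0).var() - x.var()) <= 0.05 * x.var()

    def test_notch_frequency_validated(self):
        with pytest.raises(ValueError):
            notch(np.zeros(100), 200.0, 150.0)


class TestDEGaussian:
    def test_unit_variance_closed_form(self):
        assert de_gaussian(1.0) == pytest.approx(0.5 * math.log(2 * math.pi * math.e))
        assert de_gaussian(1.0) == pytest.approx(1.41894, abs=1e-5)

    def test_log_identity_scaling(self):
        s0 = 0.37
        assert de_gaussian(math.e**2 * s0) == pytest.approx(de_gaussian(s0) + 1.0)

    def test_zero_entropy_variance(self):
        assert de_gaussian(1.0 / (2 * math.pi * math.e)) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            de_gaussian(0.0)
        with pytest.raises(ValueError):
            de_gaussian(-1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        var=st.floats(1e-6, 1e6),
        scale=st.floats(1e-3, 1e3),
    )
    def test_variance_scaling_property(self, var, scale):
        # DE(s * var) = DE(var) + ln(sqrt(s)) for any positive scale
        assert de_gaussian(scale * var) == pytest.approx(
            de_gaussian(var) + 0.5 * math.log(scale), abs=1e-9
        )


def _noise_epochs(n_epochs, n_channels, n_samples, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return EpochedEEG(
        data=scale * rng.standard_normal((n_epochs, n_channels, n_samples)),
        fs=200.0,
        channel_names=[f"c{i}" for i in range(n_channels)],
        labels=np.zeros(n_epochs, dtype=int),
        block_ids=np.zeros(n_epochs, dtype=int),
    )


class TestExtractBandDE:
    @pytest.mark.parametrize("n_channels,expected", [(62, 310), (60, 300)])
    def test_feature_dimensionality(self, n_channels, expected):
        eeg = _noise_epochs(2, n_channels, 1000)
        de = extract_band_de(eeg)
        assert de.flattened().shape == (2, expected)

    def test_matches_direct_variance_of_filtered_signal(self):
        eeg = _noise_epochs(3, 2, 1000, seed=5)
        de = extract_band_de(eeg, bands=[ALPHA])
        filtered = bandpass(eeg.data, eeg.fs, ALPHA)
        expected = de_gaussian(filtered.var(axis=-1, ddof=1))
        np.testing.assert_allclose(de.values[:, :, 0], expected, atol=1e-12)

    def test_amplitude_scaling_adds_log_scale(self):
        eeg1 = _noise_epochs(2, 2, 1000, seed=6)
        eeg2 = _noise_epochs(2, 2, 1000, seed=6, scale=3.0)
        d1 = extract_band_de(eeg1).values
        d2 = extract_band_de(eeg2).values
        np.testing.assert_allclose(d2 - d1, math.log(3.0), atol=1e-9)

    def test_channel_permutation_equivariance(self):
        eeg = _noise_epochs(2, 4, 1000, seed=7)
        perm = np.array([2, 0, 3, 1])
        permuted = EpochedEEG(
            data=eeg.data[:, perm, :],
            fs=eeg.fs,
            channel_names=[eeg.channel_names[i] for i in perm],
            labels=eeg.labels,
            block_ids=eeg.block_ids,
        )
        d = extract_band_de(eeg).values
        dp = extract_band_de(permuted).values
        np.testing.assert_allclose(dp, d[:, perm, :], atol=1e-12)

    def test_gaussian_closed_form_convergence(self):
        # wide band on long iid Gaussian epochs: filter-variance DE converges
        # to 0.5*ln(2*pi*e*sigma_band^2) of the filtered signal
        wide = BandDefinition("wide", 1.0, 90.0)
        eeg = _noise_epochs(1, 1, 100_000, seed=8)
        de = extract_band_de(eeg, bands=[wide]).values[0, 0, 0]
        filtered = bandpass(eeg.data[0, 0], eeg.fs, wide)
        assert de == pytest.approx(de_gaussian(filtered.var(ddof=1)), abs=1e-10)
        # and the filtered variance itself is close to unit variance here
        assert abs(de - de_gaussian(1.0)) < 0.1

    def test_constant_epoch_rejected(self):
        eeg = _noise_epochs(2, 2, 1000, seed=9)
        eeg.data[1, 0] = 5.0
        with pytest.raises(ValueError, match="epoch 1, channel 0"):
            extract_band_de(eeg, bands=[ALPHA])

    def test_band_edges_validated_against_nyquist(self):
        eeg = _noise_epochs(1, 1, 500, seed=4)  # fs=200 -> Nyquist 100
        with pytest.raises(ValueError, match="Nyquist"):
            extract_band_de(eeg, bands=[BandDefinition("hf", 80.0, 120.0)])

    def test_spectrum_estimator_tracks_variance_estimator(self):
        # the two estimators differ by an additive offset per band; their
        # across-epoch variation must agree
        eeg = _noise_epochs(40, 1, 1000, seed=10)
        eeg.data *= np.exp(np.linspace(0, 3, 40))[:, None, None]
        dv = extract_band_de(eeg, bands=[ALPHA], estimator="variance").values[:, 0, 0]
        ds = extract_band_de(eeg, bands=[ALPHA], estimator="spectrum").values[:, 0, 0]
        assert np.corrcoef(dv, ds)[0, 1] > 0.99
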