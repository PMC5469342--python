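"""Empirical mode decomposition: extrema, envelopes, sifting."""

import numpy as np
import pytest

from gammasift.emd import (
    EMDConfig,
    SamplingMarginWarning,
    check_sampling_margin,
    envelope,
    find_extrema,
    is_imf,
    mean_frequency,
    sift,
)

FS = 2048.0


def brute_force_extrema(x):
    """Independent O(n) scan used as the oracle for find_extrema."""
    maxima, minima = [], []
    for i in range(1, len(x) - 1):
        if x[i - 1] < x[i] > x[i + 1]:
            maxima.append(i)
        elif x[i - 1] > x[i] < x[i + 1]:
            minima.append(i)
    return maxima, minima


class TestFindExtrema:
    def test_hand_checked_zigzag(self):
        maxima, minima = find_extrema(np.array([0.0, 1.0, 0.0, -1.0, 0.0]))
        assert list(maxima) == [1] and list(minima) == [3]

    def test_monotone_ramp_has_none(self):
        maxima, minima = find_extrema(np.arange(50.0))
        assert maxima.size == 0 and minima.size == 0

    def test_one_sine_period_matches_brute_force(self):
        x = np.sin(2 * np.pi * np.arange(64) / 64)
        maxima, minima = find_extrema(x)
        bm, bn = brute_force_extrema(x)
        assert list(maxima) == bm == [16]
        assert list(minima) == bn == [48]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_noise(self, seed):
        x = np.random.default_rng(seed).standard_normal(500)
        maxima, minima = find_extrema(x)
        bm, bn = brute_force_extrema(x)
        assert list(maxima) == bm and list(minima) == bn

    def test_plateau_counts_once_at_midpoint(self):
        x = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        maxima, minima = find_extrema(x)
        assert list(maxima) == [3] and minima.size == 0


class TestEnvelope:
    def test_collinear_extrema_give_constant(self):
        x = np.sin(2 * np.pi * 8 * np.arange(1024) / 1024)
        maxima, _ = find_extrema(x)
        ue = envelope(x, maxima)
        assert np.allclose(ue[maxima[0] : maxima[-1]], x[maxima[0]], atol=1e-2)

    def test_upper_envelope_of_sine_near_amplitude(self):
        t = np.arange(int(2 * FS)) / FS
        x = 3.0 * np.sin(2 * np.pi * 10 * t)  # 20 periods
        maxima, _ = find_extrema(x)
        ue = envelope(x, maxima)
        interior = ue[int(0.1 * FS) : int(1.9 * FS)]
        assert np.all(np.abs(interior - 3.0) < 0.02 * 3.0)

    def test_two_extrema_degenerate_to_line(self):
        x = np.zeros(100)
        x[20], x[70] = 1.0, 2.0
        line = envelope(x, np.array([20, 70]), boundary="none")
        expected = np.interp(np.arange(100), [20, 70], [1.0, 2.0])
        np.testing.assert_allclose(line, expected)

    def test_no_extrema_signals_monotone(self):
        assert envelope(np.arange(10.0), np.array([], dtype=int)) is None


class TestIsImf:
    def test_pure_sine_qualifies(self, make_tone):
        assert is_imf(make_tone(40.0))

    def test_offset_sine_fails_zero_crossing_balance(self, make_tone):
        assert not is_imf(make_tone(40.0) + 5.0)

    def test_constant_fails(self):
        assert not is_imf(np.full(100, 2.0))


class TestSift:
    def test_constant_yields_no_imfs(self):
        dec = sift(np.full(100, 3.0), fs=FS)
        assert dec.n_imfs == 0
        np.testing.assert_array_equal(dec.residue, np.full(100, 3.0))

    def test_two_tone_separation(self, t_2s):
        hi = np.sin(2 * np.pi * 40 * t_2s)
        lo = np.sin(2 * np.pi * 4 * t_2s)
        dec = sift(hi + lo, fs=FS)
        assert np.corrcoef(dec.imfs[0], hi)[0, 1] > 0.95
        assert np.corrcoef(dec.imfs[1], lo)[0, 1] > 0.95

    @pytest.mark.parametrize("seed", range(8))
    def test_reconstruction_identity(self, seed):
        x = np.random.default_rng(seed).standard_normal(4096)
        dec = sift(x, fs=FS)
        err = np.abs(dec.reconstruct() - x).max() / np.abs(x).max()
        assert err < 1e-8

    def test_every_imf_satisfies_the_mode_conditions(self):
        x = np.random.default_rng(42).standard_normal(4096)
        dec = sift(x, fs=FS)
        assert dec.n_imfs >= 3
        for imf in dec.imfs:
            assert is_imf(imf)

    def test_mean_frequency_is_nonincreasing_across_modes(self):
        rng = np.random.default_rng(2)
        t = np.arange(4096) / FS
        x = rng.standard_normal(4096) + 5 * np.sin(2 * np.pi * 10 * t)
        dec = sift(x, fs=FS)
        mfs = [mean_frequency(imf, FS) for imf in dec.imfs]
        assert all(a >= b for a, b in zip(mfs, mfs[1:]))

    def test_max_imfs_cap_respected(self):
        x = np.random.default_rng(3).standard_normal(4096)
        dec = sift(x, EMDConfig(max_imfs=2), fs=FS)
        assert dec.n_imfs <= 2

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            sift(np.array([0.0, np.inf] * 8))


class TestMeanFrequency:
    def test_pure_tone(self, make_tone):
        assert abs(mean_frequency(make_tone(40.0), FS) - 40.0) < 1.0

    def test_wider_noise_band_has_higher_mean(self):
        from gammasift.preprocess import PreprocessConfig, bandpass_notch

        rng = np.random.default_rng(9)
        x = rng.standard_normal(8192)
        wide = bandpass_notch(x, FS, PreprocessConfig(bandpass_hz=(1.0, 100.0)))
        narrow = bandpass_notch(x, FS, PreprocessConfig(bandpass_hz=(1.0, 50.0)))
        assert mean_frequency(wide, FS) > mean_frequency(narrow, FS)

    def test_dc_is_excluded(self, make_tone):
        x = 100.0 + 0.01 * make_tone(40.0)
        assert abs(mean_frequency(x, FS) - 40.0) < 1.0

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            mean_frequency(np.zeros(100), FS)


class TestSamplingMargin:
    def test_sufficient_rate_passes_silently(self, recwarn):
        assert check_sampling_margin(2048.0, 60.0)
        assert not recwarn.list

    def test_marginal_rate_warns(self):
        with pytest.warns(SamplingMarginWarning):
            assert not check_sampling_margin(200.0, 60.0)
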