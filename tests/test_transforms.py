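"""Window, STFT and MODWT correctness.

The MODWT checks rest on a brute-force oracle: the level-j coefficient
series is recomputed by direct circular convolution with the explicitly
upsampled-and-chained equivalent filter, with no pyramid involved.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seiztype import (
    SignalSegment,
    WaveletFilterBank,
    band_edges,
    hann_window,
    modwt,
    modwt_mra,
    segment_windows,
    spectrogram,
)
from seiztype.exceptions import InvalidArgumentError, ShortSegmentError


def equivalent_level_filter(bank: WaveletFilterBank, level: int, kind: str) -> np.ndarray:
    """Level-j MODWT filter built by upsampled convolution of unit filters."""
    g = bank.modwt_scaling
    top = bank.modwt_wavelet if kind == "wavelet" else g
    chain = np.array([1.0])
    for k in range(level - 1):
        upsampled = np.zeros((g.size - 1) * 2**k + 1)
        upsampled[:: 2**k] = g
        chain = np.convolve(chain, upsampled)
    top_up = np.zeros((top.size - 1) * 2 ** (level - 1) + 1)
    top_up[:: 2 ** (level - 1)] = top
    return np.convolve(chain, top_up)


def brute_force_modwt(x: np.ndarray, bank: WaveletFilterBank, levels: int):
    n = x.size
    details = []
    for j in range(1, levels + 1):
        taps = equivalent_level_filter(bank, j, "wavelet")
        details.append(
            np.array(
                [sum(taps[l] * x[(t - l) % n] for l in range(taps.size)) for t in range(n)]
            )
        )
    taps = equivalent_level_filter(bank, levels, "scaling")
    scaling = np.array(
        [sum(taps[l] * x[(t - l) % n] for l in range(taps.size)) for t in range(n)]
    )
    return details, scaling


class TestHannWindow:
    def test_midpoint_of_three_is_one(self):
        assert hann_window(3).values[1] == pytest.approx(1.0)

    def test_four_point_values(self):
        expected = [0.3455, 0.9045, 0.9045, 0.3455]
        assert hann_window(4).values == pytest.approx(expected, abs=5e-5)

    @given(st.integers(min_value=1, max_value=257))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_and_bounded(self, n):
        w = hann_window(n).values
        assert np.allclose(w, w[::-1])
        assert np.all((w > 0) & (w <= 1))

    def test_rejects_empty(self):
        with pytest.raises(InvalidArgumentError):
            hann_window(0)


class TestSegmentWindows:
    @pytest.mark.parametrize(
        "n,window_s,overlap,expected",
        [(1600, 0.5, 50, 15), (1600, 0.5, 0, 8), (1600, 1.0, 25, 5), (1600, 1.0, 50, 7)],
    )
    def test_window_counts(self, n, window_s, overlap, expected):
        seg = SignalSegment(np.zeros(n) + np.arange(n) % 2, 400.0)
        windows = segment_windows(seg, window_s, overlap)
        assert len(windows) == expected
        width = int(window_s * 400)
        assert all(stop - start == width for start, stop in windows)
        assert windows[-1][1] <= n

    def test_short_segment_raises(self):
        seg = SignalSegment(np.arange(100, dtype=float), 400.0)
        with pytest.raises(ShortSegmentError):
            segment_windows(seg, 0.5, 0)

    def test_unusual_overlap_warns(self):
        seg = SignalSegment(np.arange(400, dtype=float), 400.0)
        with pytest.warns(UserWarning):
            segment_windows(seg, 0.5, 10)


class TestSpectrogram:
    def test_dc_signal_peaks_at_zero_hz(self):
        seg = SignalSegment(np.full(800, 3.0), 400.0)
        spec = spectrogram(seg, hann_window(200), hop=100)
        assert np.all(np.argmax(spec.power, axis=1) == 0)

    def test_pure_tone_peaks_at_tone_bin(self):
        t = np.arange(1600) / 400.0
        seg = SignalSegment(np.sin(2 * np.pi * 10 * t), 400.0)
        spec = spectrogram(seg, hann_window(200), hop=100)
        peak_bins = np.argmax(spec.power, axis=1)
        assert np.all(spec.frequencies_hz[peak_bins] == 10.0)  # 2 Hz bins

    def test_tone_power_concentrates_near_tone(self):
        t = np.arange(1600) / 400.0
        seg = SignalSegment(np.sin(2 * np.pi * 37 * t), 400.0)
        spec = spectrogram(seg, hann_window(200), hop=100)
        freqs = spec.frequencies_hz
        near = np.abs(freqs - 37.0) <= 2 * (freqs[1] - freqs[0])
        fraction = spec.power[:, near].sum(axis=1) / spec.power.sum(axis=1)
        assert np.all(fraction >= 0.80)

    def test_silence_is_floored_not_nan(self):
        seg = SignalSegment(np.zeros(400), 400.0)
        spec = spectrogram(seg, hann_window(200), hop=200)
        assert np.all(np.isfinite(spec.log_power))
        assert np.all(spec.log_power == np.log(1e-12))


class TestModwt:
    def test_constant_signal_has_null_details(self):
        seg = SignalSegment(np.full(256, 7.3), 400.0)
        dec = modwt(seg, levels=4)
        for w in dec.wavelet_coeffs:
            assert np.max(np.abs(w)) < 1e-10

    def test_unit_impulse_conserves_energy(self):
        x = np.zeros(256)
        x[100] = 1.0
        dec = modwt(SignalSegment(x, 400.0), levels=6)
        assert dec.energy == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("n,levels", [(128, 4), (256, 6), (512, 6)])
    def test_matches_brute_force_oracle(self, n, levels, rng):
        x = rng.standard_normal(n)
        bank = WaveletFilterBank()
        with np.errstate(all="ignore"):
            dec = modwt(x, bank, levels)
        details, scaling = brute_force_modwt(x, bank, levels)
        for ours, oracle in zip(dec.wavelet_coeffs, details):
            assert np.max(np.abs(ours - oracle)) < 1e-10
        assert np.max(np.abs(dec.scaling_coeffs - scaling)) < 1e-10

    def test_filters_match_established_db4(self):
        pywt = pytest.importorskip("pywt")
        bank = WaveletFilterBank()
        ref = pywt.Wavelet("db4")
        # pywt stores decomposition filters reversed relative to the
        # l-indexed convolution convention used here
        assert np.allclose(bank.scaling, np.array(ref.dec_lo)[::-1], atol=1e-12)
        assert np.allclose(bank.wavelet, np.array(ref.dec_hi)[::-1], atol=1e-12)

    def test_shift_invariance(self, rng):
        x = rng.standard_normal(256)
        dec = modwt(x, levels=3)
        shifted = modwt(np.roll(x, 17), levels=3)
        for a, b in zip(dec.wavelet_coeffs, shifted.wavelet_coeffs):
            assert np.allclose(np.roll(a, 17), b, atol=1e-12)

    def test_rejects_bad_levels(self):
        with pytest.raises(InvalidArgumentError):
            modwt(np.ones(64), levels=0)


class TestModwtMra:
    @pytest.mark.parametrize("seed", range(5))
    def test_perfect_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(64, 1024))
        levels = int(rng.integers(1, 7))
        x = rng.standard_normal(n)
        with np.errstate(all="ignore"):
            dec = modwt_mra(modwt(x, levels=levels))
        recon = sum(dec.details) + dec.approximation
        assert np.max(np.abs(recon - x)) < 1e-8

    def test_constant_signal_lives_in_approximation(self):
        x = np.full(512, 2.5)
        dec = modwt_mra(modwt(x, levels=6))
        assert np.allclose(dec.approximation, x, atol=1e-8)
        for d in dec.details:
            assert np.max(np.abs(d)) < 1e-8

    def test_ten_hz_tone_peaks_in_d5(self):
        t = np.arange(512) / 400.0
        x = np.sin(2 * np.pi * 10 * t)
        dec = modwt_mra(modwt(SignalSegment(x, 400.0), levels=6))
        energies = [np.sum(d**2) for d in dec.details]
        assert int(np.argmax(energies)) == 4  # D5: 6.25-12.5 Hz

    def test_bank_mismatch_rejected(self, rng):
        dec = modwt(rng.standard_normal(128), levels=2)
        other = WaveletFilterBank(scaling=np.array([1.0, 1.0]) / np.sqrt(2.0))
        with pytest.raises(InvalidArgumentError):
            modwt_mra(dec, other)


class TestBandEdges:
    def test_reference_configuration(self):
        edges = dict((name, (lo, hi)) for name, lo, hi in band_edges(400, 6))
        assert edges["D1"] == (100.0, 200.0)
        assert edges["D2"] == (50.0, 100.0)
        assert edges["D6"] == (3.125, 6.25)
        assert edges["A6"] == (0.0, 3.125)
        assert len(edges) == 7

    def test_minimal_configuration(self):
        assert band_edges(2, 1)[0] == ("D1", 0.5, 1.0)

    def test_rejects_bad_arguments(self):
        with pytest.raises(InvalidArgumentError):
            band_edges(0, 6)
        with pytest.raises(InvalidArgumentError):
            band_edges(400, 0)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_energy_conservation_property(seed):
    """MODWT conserves energy for arbitrary signals (circular boundary)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(64, 512))
    x = rng.standard_normal(n) * rng.uniform(0.1, 10)
    with np.errstate(all="ignore"):
        dec = modwt(x, levels=int(rng.integers(1, 7)))
    assert dec.energy == pytest.approx(np.sum(x**2), rel=1e-10)
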