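"""Time-frequency machinery: Hann window, discrete STFT, and the maximal
overlap discrete wavelet transform (MODWT).

The MODWT is the undecimated, shift-invariant variant of the discrete
wavelet transform: every level's coefficient series has the length of the
input, so windowed statistics of the coefficients line up sample-for-sample
with the original series. We implement the pyramid algorithm with circular
(periodic) boundary treatment and the Percival-Walden normalization, in
which the level-j filters carry an overall ``2**(-j/2)`` scaling. Under
these conventions the transform conserves energy,

    sum_j ||W_j||^2 + ||V_J||^2 == ||X||^2,

and the multiresolution analysis (MRA) details and final approximation
sum back to the input exactly (up to round-off):

    X == sum_j D_j + A_J.

For a sampling rate ``fs`` the level-j detail series D_j occupies the
nominal band [fs/2**(j+1), fs/2**j] and the approximation A_J the band
[0, fs/2**(J+1)]; at 400 Hz with J = 6 this is the familiar
D1 = 100-200 Hz down to A6 = 0-3.125 Hz ladder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError, ShortSegmentError
from .segment import SignalSegment

__all__ = [
    "WindowFunction",
    "Spectrogram",
    "WaveletFilterBank",
    "ModwtDecomposition",
    "hann_window",
    "segment_windows",
    "spectrogram",
    "modwt",
    "modwt_mra",
    "band_edges",
    "DB4_SCALING_FILTER",
]

# Daubechies extremal-phase scaling (low-pass) filter with 4 vanishing
# moments ("db4", 8 taps), normalized so the taps sum to sqrt(2).
DB4_SCALING_FILTER: np.ndarray = np.array(
    [
        0.23037781330885523,
        0.71484657055254153,
        0.63088076792959036,
        -0.02798376941698385,
        -0.18703481171888114,
        0.03084138183598697,
        0.03288301166698295,
        -0.01059740178499728,
    ]
)

#: Floor applied to |X|^2 before taking the log of a spectrogram.
LOG_POWER_FLOOR = 1e-12


@dataclass
class WindowFunction:
    """A taper ``w(n)``, ``n = 1..N`` (1-based convention, endpoints nonzero)."""

    values: np.ndarray
    kind: str = "hann"

    @property
    def length(self) -> int:
        return self.values.size


def hann_window(n_samples: int) -> WindowFunction:
    """Hann taper ``w(n) = 0.5 * (1 - cos(2 pi n / (N + 1)))`` for n = 1..N.

    The 1-based convention keeps both endpoints nonzero (for N = 3 the
    middle sample is exactly 1). Raises for ``n_samples < 1``.
    """
    if n_samples < 1:
        raise InvalidArgumentError("window length must be >= 1")
    n = np.arange(1, n_samples + 1)
    values = 0.5 * (1.0 - np.cos(2.0 * np.pi * n / (n_samples + 1)))
    return WindowFunction(values=values, kind="hann")


def segment_windows(
    segment: SignalSegment, window_s: float, overlap_pct: float
) -> list[tuple[int, int]]:
    """Half-open index ranges of analysis windows over a segment.

    Window length ``W = window_s * rate`` samples, hop
    ``H = round(W * (1 - overlap/100))``. Windows that would overrun the
    segment are dropped, giving ``floor((len - W) / H) + 1`` windows.
    """
    rate = segment.sampling_rate_hz
    w_float = window_s * rate
    width = int(round(w_float))
    if width < 1 or abs(w_float - width) > 1e-9:
        raise InvalidArgumentError(
            f"window_s * rate must be a positive integer, got {w_float}"
        )
    if overlap_pct not in (0, 25, 50):
        warnings.warn(
            f"overlap_pct={overlap_pct} is outside the usual {{0, 25, 50}} grid",
            stacklevel=2,
        )
    if not (0 <= overlap_pct < 100):
        raise InvalidArgumentError("overlap_pct must be in [0, 100)")
    hop = int(round(width * (1.0 - overlap_pct / 100.0)))
    n = len(segment)
    if n < width:
        raise ShortSegmentError(
            f"segment of {n} samples is shorter than one {width}-sample window"
        )
    starts = range(0, n - width + 1, hop)
    return [(s, s + width) for s in starts]


@dataclass
class Spectrogram:
    """Discrete STFT coefficients with their log-power surface."""

    coefficients: np.ndarray  # complex, (n_frames, n_bins)
    log_power: np.ndarray  # (n_frames, n_bins)
    frequencies_hz: np.ndarray  # (n_bins,), 0 .. fs/2
    times_s: np.ndarray  # (n_frames,) frame centers

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2


def spectrogram(
    segment: SignalSegment, window: WindowFunction, hop: int
) -> Spectrogram:
    """Discrete short-time Fourier transform with a per-frame taper.

    One-sided spectrum, DFT length equal to the window length (no zero
    padding), bin ``k`` at frequency ``k * fs / N``. The log-power surface
    is ``log(max(|X|^2, eps))`` with ``eps = 1e-12`` so silent frames stay
    finite.
    """
    if hop < 1:
        raise InvalidArgumentError("hop must be >= 1")
    width = window.length
    n = len(segment)
    if n < width:
        raise ShortSegmentError("segment shorter than the analysis window")
    starts = np.arange(0, n - width + 1, hop)
    frames = np.stack([segment.samples[s : s + width] for s in starts])
    tapered = frames * window.values
    coeffs = np.fft.rfft(tapered, axis=1)
    power = np.abs(coeffs) ** 2
    log_power = np.log(np.maximum(power, LOG_POWER_FLOOR))
    freqs = np.arange(coeffs.shape[1]) * segment.sampling_rate_hz / width
    times = (starts + width / 2.0) / segment.sampling_rate_hz
    return Spectrogram(
        coefficients=coeffs,
        log_power=log_power,
        frequencies_hz=freqs,
        times_s=times,
    )


@dataclass
class WaveletFilterBank:
    """DWT base filters and their MODWT rescalings.

    ``scaling`` (g, low-pass) sums to sqrt(2) and ``wavelet`` (h,
    high-pass) sums to 0; the MODWT unit-level filters are the base
    filters divided by sqrt(2).
    """

    name: str = "db4"
    scaling: np.ndarray = field(default_factory=lambda: DB4_SCALING_FILTER.copy())
    wavelet: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.scaling, dtype=float)
        if abs(g.sum() - np.sqrt(2.0)) > 1e-10:
            raise InvalidArgumentError("scaling filter must sum to sqrt(2)")
        # quadrature mirror: h_l = (-1)^l g_{L-1-l}
        length = g.size
        self.wavelet = ((-1.0) ** np.arange(length)) * g[::-1]

    @property
    def width(self) -> int:
        return self.scaling.size

    @property
    def modwt_scaling(self) -> np.ndarray:
        return self.scaling / np.sqrt(2.0)

    @property
    def modwt_wavelet(self) -> np.ndarray:
        return self.wavelet / np.sqrt(2.0)

    def level_filter_width(self, level: int) -> int:
        """Width ``L_j = (2^j - 1)(L - 1) + 1`` of the equivalent level-j filter."""
        return (2**level - 1) * (self.width - 1) + 1


@dataclass
class ModwtDecomposition:
    """MODWT coefficients (and, after MRA, detail/approximation series).

    ``wavelet_coeffs[j]`` is the level-(j+1) series W_{j+1}; every series
    has the input's length.
    """

    wavelet_coeffs: list[np.ndarray]
    scaling_coeffs: np.ndarray  # V_J
    levels: int
    bank: WaveletFilterBank
    sampling_rate_hz: float
    details: list[np.ndarray] | None = None  # D_1..D_J after MRA
    approximation: np.ndarray | None = None  # A_J after MRA

    def series(self) -> dict[str, np.ndarray]:
        """Coefficient series keyed ``D1..DJ, AJ`` (W_j as the D_j band proxy)."""
        out = {f"D{j + 1}": w for j, w in enumerate(self.wavelet_coeffs)}
        out[f"A{self.levels}"] = self.scaling_coeffs
        return out

    @property
    def energy(self) -> float:
        total = sum(float(np.sum(w**2)) for w in self.wavelet_coeffs)
        return total + float(np.sum(self.scaling_coeffs**2))


def _circular_filter_down(series: np.ndarray, taps: np.ndarray, stride: int) -> np.ndarray:
    """``y[t] = sum_l taps[l] * series[(t - stride*l) mod N]`` (analysis step)."""
    out = np.zeros_like(series)
    for tap_index, tap in enumerate(taps):
        out += tap * np.roll(series, stride * tap_index)
    return out


def _circular_filter_up(series: np.ndarray, taps: np.ndarray, stride: int) -> np.ndarray:
    """``y[t] = sum_l taps[l] * series[(t + stride*l) mod N]`` (synthesis step)."""
    out = np.zeros_like(series)
    for tap_index, tap in enumerate(taps):
        out += tap * np.roll(series, -stride * tap_index)
    return out


def modwt(
    segment: SignalSegment | np.ndarray,
    bank: WaveletFilterBank | None = None,
    levels: int = 6,
    sampling_rate_hz: float | None = None,
) -> ModwtDecomposition:
    """Maximal overlap DWT by the pyramid algorithm, circular boundary.

    At level j the unit filters are applied with stride ``2**(j-1)`` to the
    previous level's scaling coefficients; no downsampling occurs, so every
    output series has the input length and the transform is shift
    invariant. Warns (does not fail) when the signal is shorter than the
    level-J equivalent filter, where circular wrap-around dominates.
    """
    if levels < 1:
        raise InvalidArgumentError("levels must be >= 1")
    if bank is None:
        bank = WaveletFilterBank()
    if isinstance(segment, SignalSegment):
        x = segment.samples
        rate = segment.sampling_rate_hz
    else:
        x = np.asarray(segment, dtype=float)
        rate = float(sampling_rate_hz) if sampling_rate_hz else 1.0
    if x.size < 1:
        raise InvalidArgumentError("empty input")
    if x.size < bank.level_filter_width(levels):
        warnings.warn(
            f"signal length {x.size} is below the level-{levels} filter width "
            f"{bank.level_filter_width(levels)}; boundary wrap-around dominates",
            stacklevel=2,
        )
    h = bank.modwt_wavelet
    g = bank.modwt_scaling
    wavelet_coeffs: list[np.ndarray] = []
    v = x.astype(float)
    for j in range(1, levels + 1):
        stride = 2 ** (j - 1)
        wavelet_coeffs.append(_circular_filter_down(v, h, stride))
        v = _circular_filter_down(v, g, stride)
    return ModwtDecomposition(
        wavelet_coeffs=wavelet_coeffs,
        scaling_coeffs=v,
        levels=levels,
        bank=bank,
        sampling_rate_hz=rate,
    )


def modwt_mra(
    decomposition: ModwtDecomposition, bank: WaveletFilterBank | None = None
) -> ModwtDecomposition:
    """Fill per-level detail series D_j and approximation A_J (MRA).

    Each detail is the synthesis chain applied to that level's wavelet
    coefficients alone; the approximation is the chain applied to V_J. The
    series then satisfy ``X == sum_j D_j + A_J`` to round-off.
    """
    if bank is None:
        bank = decomposition.bank
    if bank.width != decomposition.bank.width or not np.allclose(
        bank.scaling, decomposition.bank.scaling
    ):
        raise InvalidArgumentError("filter bank does not match the decomposition")
    h = bank.modwt_wavelet
    g = bank.modwt_scaling

    def synthesize(level: int, series: np.ndarray, taps_top: np.ndarray) -> np.ndarray:
        out = _circular_filter_up(series, taps_top, 2 ** (level - 1))
        for j in range(level - 1, 0, -1):
            out = _circular_filter_up(out, g, 2 ** (j - 1))
        return out

    details = [
        synthesize(j + 1, w, h) for j, w in enumerate(decomposition.wavelet_coeffs)
    ]
    approximation = synthesize(
        decomposition.levels, decomposition.scaling_coeffs, g
    )
    decomposition.details = details
    decomposition.approximation = approximation
    return decomposition


def band_edges(sampling_rate_hz: float, levels: int) -> list[tuple[str, float, float]]:
    """Nominal frequency bands ``(name, low_hz, high_hz)`` for D1..DJ, AJ.

    D_j spans [fs/2**(j+1), fs/2**j]; A_J spans [0, fs/2**(J+1)]. At
    400 Hz with six levels: D1 = 100-200 Hz, ..., D6 = 3.125-6.25 Hz,
    A6 = 0-3.125 Hz.
    """
    if sampling_rate_hz <= 0:
        raise InvalidArgumentError("sampling rate must be positive")
    if levels < 1:
        raise InvalidArgumentError("levels must be >= 1")
    edges = [
        (f"D{j}", sampling_rate_hz / 2 ** (j + 1), sampling_rate_hz / 2**j)
        for j in range(1, levels + 1)
    ]
    edges.append((f"A{levels}", 0.0, sampling_rate_hz / 2 ** (levels + 1)))
    return edges
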