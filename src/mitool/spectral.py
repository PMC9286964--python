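"""Frequency and time-frequency features: periodogram, STFT power spectral
density, and Mallat pyramidal wavelet decomposition with sub-band accounting.

Scaling conventions: the periodogram is |DFT|²/N (one-sided, interior bins
doubled so the one-sided sum equals the signal energy); the STFT power
spectral density is |windowed-frame DFT|²/(2π).  The discrete wavelet
transform uses PyWavelets' pyramidal filter bank with symmetric padding; an
L-level decomposition splits [0, fs/2] into L+1 dyadic sub-bands
A_L: [0, fs/2^(L+1)] and D_j: [fs/2^(j+1), fs/2^j].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps


@dataclass
class Periodogram:
    freqs: np.ndarray  # Hz, one-sided grid [0, fs/2]
    power: np.ndarray  # one-sided power, sums to signal energy
    n: int


@dataclass
class Spectrogram:
    times: np.ndarray  # s, frame centers, uniform hop
    freqs: np.ndarray  # Hz
    psd: np.ndarray  # time × frequency, |STFT|²/(2π)
    window: dict  # name, length (samples), hop (samples)


@dataclass
class WaveletDecomposition:
    """One approximation plus L detail coefficient sequences.

    ``subbands`` maps each component name (``A_L``, ``D_L``, …, ``D_1``) to
    its (low, high) frequency band in Hz; the bands tile (0, fs/2].
    """

    levels: int
    approx: np.ndarray
    details: list[np.ndarray]  # [cD_L, ..., cD_1]
    wavelet: str
    fs: float
    subbands: dict[str, tuple[float, float]]
    mode: str = "symmetric"

    @property
    def components(self) -> dict[str, np.ndarray]:
        out = {f"A_{self.levels}": self.approx}
        for k, cd in enumerate(self.details):
            out[f"D_{self.levels - k}"] = cd
        return out


def periodogram(x: np.ndarray, fs: float) -> Periodogram:
    """Power-spectrum estimate |X_N(ω)|²/N of a single-channel signal."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("periodogram requires a 1-D signal of at least 2 samples")
    n = x.size
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n
    # fold negative frequencies in: double interior bins (and Nyquist only
    # when n is odd, i.e. when the last bin is not the unpaired fs/2 bin)
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return Periodogram(freqs=freqs, power=power, n=n)


def stft_psd(x: np.ndarray, fs: float, window_len: int, hop: int) -> Spectrogram:
    """Hanning-windowed short-time Fourier power spectral density.

    Frames start at 0, hop, 2·hop, … while they fit; each frame's PSD is
    |DFT(frame · w)|²/(2π); frame times are the window centers.
    """
    x = np.asarray(x, dtype=float)
    if window_len > x.size:
        raise ValueError(f"window ({window_len}) longer than signal ({x.size})")
    if not 1 <= hop <= window_len:
        raise ValueError("hop must satisfy 1 <= hop <= window_len")
    w = sps.get_window("hann", window_len, fftbins=True)
    starts = np.arange(0, x.size - window_len + 1, hop)
    frames = np.stack([x[s : s + window_len] * w for s in starts])
    psd = np.abs(np.fft.rfft(frames, axis=1)) ** 2 / (2.0 * np.pi)
    times = (starts + window_len / 2.0) / fs
    freqs = np.fft.rfftfreq(window_len, d=1.0 / fs)
    return Spectrogram(times=times, freqs=freqs, psd=psd,
                       window={"name": "hann", "length": window_len, "hop": hop})


def subband_table(fs: float, levels: int) -> dict[str, tuple[float, float]]:
    """Dyadic sub-band edges of an L-level decomposition at sampling rate fs."""
    bands = {f"A_{levels}": (0.0, fs / 2 ** (levels + 1))}
    for j in range(levels, 0, -1):
        bands[f"D_{j}"] = (fs / 2 ** (j + 1), fs / 2 ** j)
    return bands


def wavedec(x: np.ndarray, fs: float, levels: int, wavelet: str = "db4") -> WaveletDecomposition:
    """Mallat pyramidal decomposition into A_L and D_L … D_1."""
    x = np.asarray(x, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if x.size < 2**levels:
        raise ValueError(f"signal of {x.size} samples too short for {levels} levels")
    with warnings.catch_warnings():
        # pywt warns when levels exceed its conservative recommendation; the
        # filter bank still reconstructs perfectly down to length >= 2^L
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=levels)
    return WaveletDecomposition(
        levels=levels,
        approx=coeffs[0],
        details=list(coeffs[1:]),
        wavelet=wavelet,
        fs=fs,
        subbands=subband_table(fs, levels),
    )


def reconstruct(dec: WaveletDecomposition, length: int | None = None) -> np.ndarray:
    """Inverse of :func:`wavedec` (perfect reconstruction up to rounding)."""
    x = pywt.waverec([dec.approx] + dec.details, dec.wavelet, mode=dec.mode)
    if length is not None:
        x = x[:length]
    return x


def subband_energy_features(dec: WaveletDecomposition) -> np.ndarray:
    """Per-component energies and relative energies as a feature vector.

    Ordered A_L, D_L, …, D_1: first the L+1 absolute energies Σc², then the
    L+1 relative energies (zero for an all-zero decomposition).
    """
    energies = np.array([np.sum(c**2) for c in [dec.approx] + dec.details])
    total = energies.sum()
    relatives = energies / total if total > 0 else np.zeros_like(energies)
    return np.concatenate([energies, relatives])
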