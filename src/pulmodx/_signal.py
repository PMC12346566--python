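"""Low-level audio DSP: framing, STFT, mel filterbank, MFCC, phase vocoder.

Conventions (documented so the frame-count oracle is checkable):

* STFT frames use a Hann window of ``n_fft`` samples and hop ``hop``.
* Frames are *centered*: the signal is reflect-padded by ``n_fft // 2`` on
  both sides, so a signal of ``n`` samples yields ``1 + n // hop`` frames.
* The mel scale follows the HTK formula ``mel = 2595 log10(1 + f/700)``.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, irfft, rfft
from scipy.signal import resample_poly
from scipy.signal.windows import hann

DEFAULT_N_FFT = 2048
DEFAULT_HOP = 512


def n_frames(n_samples: int, hop: int = DEFAULT_HOP) -> int:
    """Number of centered STFT frames for a signal of ``n_samples``."""
    return 1 + n_samples // hop


def frame_signal(y: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    """Centered framing: reflect-pad by n_fft//2, then slide with ``hop``."""
    pad = n_fft // 2
    if len(y) < 2:
        y = np.pad(y, (0, 2 - len(y)))
    ypad = np.pad(y, pad, mode="reflect")
    frames = sliding_window_view(ypad, n_fft)[::hop]
    return frames


def stft(y: np.ndarray, n_fft: int = DEFAULT_N_FFT, hop: int = DEFAULT_HOP) -> np.ndarray:
    """Complex STFT, shape (1 + n_fft//2, n_frames)."""
    frames = frame_signal(np.asarray(y, dtype=np.float64), n_fft, hop)
    win = hann(n_fft, sym=False)
    return rfft(frames * win, axis=1).T


def istft(Z: np.ndarray, n_fft: int = DEFAULT_N_FFT, hop: int = DEFAULT_HOP,
          length: int | None = None) -> np.ndarray:
    """Inverse STFT by windowed overlap-add (matches :func:`stft`)."""
    win = hann(n_fft, sym=False)
    frames = irfft(Z.T, n=n_fft, axis=1) * win
    T = Z.shape[1]
    n_out = n_fft + hop * (T - 1)
    y = np.zeros(n_out)
    norm = np.zeros(n_out)
    w2 = win**2
    # overlap-add, vectorized chunk-wise: for offset k, the k-th hop-sized
    # slice of every frame tiles a contiguous region
    for k in range(n_fft // hop):
        y[k * hop: k * hop + T * hop] += frames[:, k * hop:(k + 1) * hop].ravel()
        norm[k * hop: k * hop + T * hop] += np.tile(
            w2[k * hop:(k + 1) * hop], T)
    y = y / np.maximum(norm, 1e-10)
    pad = n_fft // 2
    y = y[pad:-pad]
    if length is not None:
        if len(y) < length:
            y = np.pad(y, (0, length - len(y)))
        else:
            y = y[:length]
    return y


def power_spectrogram(y: np.ndarray, n_fft: int = DEFAULT_N_FFT,
                      hop: int = DEFAULT_HOP) -> np.ndarray:
    return np.abs(stft(y, n_fft, hop)) ** 2


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(sr: int, n_fft: int, n_mels: int = 128, fmin: float = 0.0,
                   fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, 1 + n_fft//2)."""
    if fmax is None:
        fmax = sr / 2.0
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.linspace(0.0, sr / 2.0, 1 + n_fft // 2)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(mid - lo, 1e-10)
        down = (hi - fft_freqs) / max(hi - mid, 1e-10)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def log_mel_spectrogram(y: np.ndarray, sr: int, n_mels: int = 64,
                        n_fft: int = DEFAULT_N_FFT, hop: int = DEFAULT_HOP) -> np.ndarray:
    S = power_spectrogram(y, n_fft, hop)
    M = mel_filterbank(sr, n_fft, n_mels) @ S
    return 10.0 * np.log10(np.maximum(M, 1e-10))


def mfcc(y: np.ndarray, sr: int, n_mfcc: int = 52, n_mels: int = 128,
         n_fft: int = DEFAULT_N_FFT, hop: int = DEFAULT_HOP) -> np.ndarray:
    """MFCC matrix of shape (n_mfcc, n_frames).

    Pipeline: power STFT -> mel filterbank -> dB -> DCT-II (orthonormal)
    along the mel axis, keeping the first ``n_mfcc`` coefficients.
    """
    if n_mfcc > n_mels:
        raise ValueError(
            f"n_mfcc={n_mfcc} exceeds the mel filterbank size n_mels={n_mels}"
        )
    logM = log_mel_spectrogram(y, sr, n_mels=n_mels, n_fft=n_fft, hop=hop)
    return dct(logM, type=2, axis=0, norm="ortho")[:n_mfcc]


def resample(y: np.ndarray, sr: int, target_sr: int) -> np.ndarray:
    """Polyphase resampling from ``sr`` to ``target_sr``."""
    if sr == target_sr:
        return np.asarray(y, dtype=np.float64)
    frac = Fraction(target_sr, sr).limit_denominator(10_000)
    return resample_poly(np.asarray(y, dtype=np.float64), frac.numerator, frac.denominator)


def phase_vocoder(Z: np.ndarray, rate: float, n_fft: int = DEFAULT_N_FFT,
                  hop: int = DEFAULT_HOP) -> np.ndarray:
    """Stretch an STFT in time by ``1/rate`` with phase accumulation."""
    n_bins, n_steps = Z.shape
    time_steps = np.arange(0, n_steps, rate)
    # expected per-hop phase advance of each bin
    phi_advance = 2.0 * np.pi * np.arange(n_bins) * hop / n_fft
    Zpad = np.pad(Z, [(0, 0), (0, 2)])
    idx = time_steps.astype(int)
    frac = time_steps - idx
    mag = (1 - frac) * np.abs(Zpad[:, idx]) + frac * np.abs(Zpad[:, idx + 1])
    dphi = (np.angle(Zpad[:, idx + 1]) - np.angle(Zpad[:, idx])
            - phi_advance[:, None])
    dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
    step_phase = phi_advance[:, None] + dphi
    phase = np.angle(Z[:, 0])[:, None] + np.concatenate(
        [np.zeros((n_bins, 1)), np.cumsum(step_phase[:, :-1], axis=1)], axis=1)
    return mag * np.exp(1j * phase)


def time_stretch_signal(y: np.ndarray, rate: float, n_fft: int = DEFAULT_N_FFT,
                        hop: int = DEFAULT_HOP) -> np.ndarray:
    """Phase-vocoder time stretch; output duration ~= len(y) / rate."""
    if rate <= 0:
        raise ValueError("stretch rate must be positive")
    Z = stft(y, n_fft, hop)
    Zs = phase_vocoder(Z, rate, n_fft, hop)
    return istft(Zs, n_fft, hop, length=int(round(len(y) / rate)))


def pitch_shift_signal(y: np.ndarray, sr: int, semitones: float,
                       n_fft: int = DEFAULT_N_FFT, hop: int = DEFAULT_HOP) -> np.ndarray:
    """Pitch shift by ``semitones`` at constant duration.

    Time-stretch by 1/factor (duration x factor), then resample back to the
    original number of samples, which multiplies all frequencies by
    ``factor = 2 ** (semitones / 12)``.
    """
    factor = 2.0 ** (semitones / 12.0)
    stretched = time_stretch_signal(y, rate=1.0 / factor, n_fft=n_fft, hop=hop)
    frac = Fraction(len(y), len(stretched)).limit_denominator(10_000)
    out = resample_poly(stretched, frac.numerator, frac.denominator)
    if len(out) < len(y):
        out = np.pad(out, (0, len(y) - len(out)))
    return out[: len(y)]
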