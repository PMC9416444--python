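"""Acoustic and articulatory feature extraction.

Acoustic features are 80-band log-mel spectrograms (FFT 1024, hop 256,
22,050 Hz audio, Slaney-style area-normalised mel filterbank spanning
0–8000 Hz, natural-log compression floored at 1e-5).  MFCCs are obtained by
an orthonormal DCT-II across the 80 log-mel bands; coefficient 0 (overall
energy) is dropped and coefficients 1..13 retained, so the cepstral distance
used for evaluation is energy-invariant.

Articulatory features are the 18 sensor-position channels linearly
interpolated onto the acoustic frame grid, stacked with their first and
second discrete time derivatives (54 channels total).

A Griffin–Lim mel-inversion hook provides waveforms from mel matrices; it
replaces a neural vocoder and its quality is deliberately outside the
package's evaluation surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct

from .data import EmaTrajectory

#: Pinned extraction parameters.  Changing any of these invalidates stored features.
MEL_CONFIG = {
    "sr": 22_050,
    "n_fft": 1024,
    "hop": 256,
    "n_mels": 80,
    "fmin": 0.0,
    "fmax": 8000.0,
    "log_floor": 1e-5,
}

#: Number of retained cepstral coefficients (DCT coefficients 1..13).
MFCC_KEEP = 13

LOG_FLOOR_VALUE = float(np.log(MEL_CONFIG["log_floor"]))


# ---------------------------------------------------------------------------
# STFT / mel filterbank
# ---------------------------------------------------------------------------

def _hann(n: int) -> np.ndarray:
    # periodic Hann window
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)


def _frame_count(n_samples: int, hop: int) -> int:
    return 1 + n_samples // hop


def stft_magnitude(audio: np.ndarray, n_fft: int = 1024, hop: int = 256) -> np.ndarray:
    """Magnitude STFT, centre-padded (reflect), shape (1 + n_fft//2, T)."""
    spec = _stft(audio, n_fft, hop)
    return np.abs(spec)


def _stft(audio: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    x = np.asarray(audio, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("audio must be non-empty mono")
    pad = n_fft // 2
    xp = np.pad(x, pad, mode="reflect") if x.size > pad else np.pad(x, pad)
    n_frames = _frame_count(x.size, hop)
    win = _hann(n_fft)
    frames = np.lib.stride_tricks.sliding_window_view(xp, n_fft)[::hop][:n_frames]
    return np.fft.rfft(frames * win, axis=1).T


def _istft(spec: np.ndarray, n_fft: int, hop: int, n_samples: int) -> np.ndarray:
    """Inverse STFT by windowed overlap-add; matches :func:`_stft` conventions."""
    win = _hann(n_fft)
    frames = np.fft.irfft(spec.T, n=n_fft, axis=1) * win
    n_frames = frames.shape[0]
    total = n_fft + (n_frames - 1) * hop
    x = np.zeros(total)
    norm = np.zeros(total)
    w2 = win**2
    for t in range(n_frames):
        x[t * hop : t * hop + n_fft] += frames[t]
        norm[t * hop : t * hop + n_fft] += w2
    x /= np.maximum(norm, 1e-10)
    pad = n_fft // 2
    return x[pad : pad + n_samples]


def _hz_to_mel(f: np.ndarray) -> np.ndarray:
    """Slaney mel scale: linear below 1 kHz, logarithmic above."""
    f = np.asarray(f, dtype=np.float64)
    mel = f / (200.0 / 3.0)
    log_region = f >= 1000.0
    mel = np.where(log_region, 15.0 + np.log(np.maximum(f, 1e-12) / 1000.0) / (np.log(6.4) / 27.0), mel)
    return mel


def _mel_to_hz(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    f = m * (200.0 / 3.0)
    log_region = m >= 15.0
    return np.where(log_region, 1000.0 * np.exp((m - 15.0) * (np.log(6.4) / 27.0)), f)


def mel_filterbank(
    sr: int = 22_050,
    n_fft: int = 1024,
    n_mels: int = 80,
    fmin: float = 0.0,
    fmax: float = 8000.0,
) -> np.ndarray:
    """Triangular mel filterbank (n_mels × (1 + n_fft//2)), Slaney area norm."""
    fft_freqs = np.linspace(0.0, sr / 2.0, 1 + n_fft // 2)
    mel_pts = np.linspace(_hz_to_mel(np.array(fmin)), _hz_to_mel(np.array(fmax)), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (hi - lo)  # equal-area normalisation
    return fb


_FB_CACHE: dict[tuple, np.ndarray] = {}


def _filterbank() -> np.ndarray:
    key = (MEL_CONFIG["sr"], MEL_CONFIG["n_fft"], MEL_CONFIG["n_mels"],
           MEL_CONFIG["fmin"], MEL_CONFIG["fmax"])
    if key not in _FB_CACHE:
        _FB_CACHE[key] = mel_filterbank(*key)
    return _FB_CACHE[key]


# ---------------------------------------------------------------------------
# Public feature extraction
# ---------------------------------------------------------------------------

def mel_spectrogram(audio: np.ndarray, sr: int = 22_050) -> np.ndarray:
    """Log-mel spectrogram, shape (T, 80), natural log floored at 1e-5.

    ``T = 1 + n_samples // 256``; frames are centred (reflect padding).
    """
    if sr != MEL_CONFIG["sr"]:
        raise ValueError(f"audio must be at {MEL_CONFIG['sr']} Hz, got {sr}")
    mag = stft_magnitude(audio, MEL_CONFIG["n_fft"], MEL_CONFIG["hop"])
    mel = _filterbank() @ mag
    return np.log(np.maximum(mel, MEL_CONFIG["log_floor"])).T


def mfcc_from_mel(mel: np.ndarray) -> np.ndarray:
    """Retained cepstra (T × 13): orthonormal DCT-II over the 80 log-mel bands,
    coefficient 0 dropped, coefficients 1..13 kept."""
    mel = np.atleast_2d(np.asarray(mel, dtype=np.float64))
    if mel.shape[1] != MEL_CONFIG["n_mels"]:
        raise ValueError(f"expected {MEL_CONFIG['n_mels']} mel bands, got {mel.shape[1]}")
    coeffs = dct(mel, type=2, axis=1, norm="ortho")
    return coeffs[:, 1 : 1 + MFCC_KEEP]


def artic_features(ema: EmaTrajectory, target_len: int) -> np.ndarray:
    """54-channel articulatory features on the acoustic frame grid.

    The 18 position channels are linearly interpolated onto ``target_len``
    uniformly spaced points spanning the utterance, then first (Δ) and second
    (ΔΔ) derivatives are taken by central differences (one-sided at the
    edges).  Column order: [positions | Δ | ΔΔ].
    """
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    pos = resample_channels(ema.samples, target_len)
    delta = np.gradient(pos, axis=0)
    ddelta = np.gradient(delta, axis=0)
    return np.concatenate([pos, delta, ddelta], axis=1)


def resample_channels(x: np.ndarray, target_len: int) -> np.ndarray:
    """Per-column linear interpolation of a (T, C) matrix to (target_len, C)."""
    x = np.asarray(x, dtype=np.float64)
    t_in = np.linspace(0.0, 1.0, x.shape[0])
    t_out = np.linspace(0.0, 1.0, target_len)
    out = np.empty((target_len, x.shape[1]))
    for c in range(x.shape[1]):
        out[:, c] = np.interp(t_out, t_in, x[:, c])
    return out


# ---------------------------------------------------------------------------
# z-score normalisation
# ---------------------------------------------------------------------------

STD_EPS = 1e-8


@dataclass
class NormStats:
    """Per-dimension mean/std fitted on a training set; std floored at 1e-8."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)


def zscore_fit(train_features: np.ndarray | list[np.ndarray]) -> NormStats:
    """Fit dimension-wise mean and standard deviation on training frames only."""
    if isinstance(train_features, (list, tuple)):
        x = np.concatenate([np.asarray(f) for f in train_features], axis=0)
    else:
        x = np.asarray(train_features)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training frames")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    if np.any(std < STD_EPS):
        warnings.warn("zero-variance feature dimension(s); std floored", stacklevel=2)
        std = np.maximum(std, STD_EPS)
    return NormStats(mean=mean, std=std)


def zscore_apply(features: np.ndarray, stats: NormStats) -> np.ndarray:
    return (np.asarray(features) - stats.mean) / stats.std


def zscore_invert(features: np.ndarray, stats: NormStats) -> np.ndarray:
    return np.asarray(features) * stats.std + stats.mean


# ---------------------------------------------------------------------------
# Mel inversion hook (Griffin–Lim)
# ---------------------------------------------------------------------------

def mel_to_audio(log_mel: np.ndarray, n_iter: int = 32) -> np.ndarray:
    """Waveform from a (T, 80) log-mel matrix via pseudo-inverse + Griffin–Lim.

    The output has ``(T - 1) * hop`` samples so that re-extraction yields
    exactly T frames.  Phase is initialised to zero, making the hook
    deterministic.  Quality is vocoder-free reconstruction only; the
    round-trip ``mel_spectrogram(mel_to_audio(M)) ≈ M`` holds to roughly
    0.1–0.3 nats mean absolute error on smooth spectra.
    """
    log_mel = np.asarray(log_mel, dtype=np.float64)
    n_fft, hop = MEL_CONFIG["n_fft"], MEL_CONFIG["hop"]
    fb = _filterbank()
    mag = np.maximum(np.linalg.pinv(fb) @ np.exp(log_mel).T, 0.0)
    n_samples = (log_mel.shape[0] - 1) * hop
    spec = mag.astype(complex)
    x = _istft(spec, n_fft, hop, n_samples)
    for _ in range(n_iter):
        phase = np.exp(1j * np.angle(_stft(x, n_fft, hop)))
        x = _istft(mag * phase, n_fft, hop, n_samples)
    return x
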