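"""Log-power mel-spectrogram front end and the device-similarity audit.

The network consumes 128-band log-power mel spectrograms computed from
32 kHz audio with a 640-sample (20 ms) Hann window, 320-sample (10 ms) hop
and a 640-point FFT. With centered (reflect-padded) framing a 2-s clip maps
to exactly (128, 201).

Pipeline per clip: pre-emphasis -> centered STFT -> power magnitude ->
mel filterbank (Slaney band spacing and area normalization by default,
HTK spacing available) -> natural-log compression with a 1e-10 floor.

``melspec_cosine_similarity`` flattens two spectrograms and returns the
cosine of their angle; the study used it to audit recording-device bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import get_window

LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class MelConfig:
    """Front-end parameters. Defaults are the pipeline's fixed operating point."""

    n_mels: int = 128
    sample_rate: int = 32_000
    win_length: int = 640
    hop_length: int = 320
    n_fft: int = 640
    preemphasis_alpha: float = 0.97
    htk: bool = False  # False = Slaney band spacing, 0 .. sr/2
    log_floor: float = LOG_FLOOR

    def __post_init__(self) -> None:
        if not (0.0 <= self.preemphasis_alpha < 1.0):
            raise ValueError("preemphasis_alpha must be in [0, 1)")
        if self.n_fft < self.win_length:
            raise ValueError("n_fft must be >= win_length")
        if self.hop_length > self.win_length:
            raise ValueError("hop_length must be <= win_length")
        if self.n_mels >= self.n_fft // 2 + 1:
            raise ValueError("n_mels must be < n_fft/2 + 1")

    def n_frames(self, n_samples: int) -> int:
        """Frame count under centered framing: 1 + floor(n/hop)."""
        return 1 + n_samples // self.hop_length


@dataclass
class MelSpectrogram:
    """Log-power mel matrix of shape (n_mels, n_frames)."""

    values: np.ndarray
    config: MelConfig
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.config.n_mels:
            raise ValueError(
                f"expected ({self.config.n_mels}, n_frames), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mel spectrogram contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def preemphasize(wave: np.ndarray, alpha: float) -> np.ndarray:
    """First-order high-pass: y[0] = x[0], y[t] = x[t] - alpha*x[t-1]."""
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must be in [0, 1)")
    wave = np.asarray(wave, dtype=np.float64)
    out = wave.copy()
    out[1:] -= alpha * wave[:-1]
    return out


def _hz_to_mel(freq: np.ndarray | float, htk: bool) -> np.ndarray:
    freq = np.asarray(freq, dtype=np.float64)
    if htk:
        return 2595.0 * np.log10(1.0 + freq / 700.0)
    # Slaney: linear below 1 kHz, logarithmic above
    f_min, f_sp = 0.0, 200.0 / 3
    mel = (freq - f_min) / f_sp
    min_log_hz = 1000.0
    min_log_mel = (min_log_hz - f_min) / f_sp
    logstep = np.log(6.4) / 27.0
    above = freq >= min_log_hz
    mel = np.where(
        above,
        min_log_mel + np.log(np.maximum(freq, min_log_hz) / min_log_hz) / logstep,
        mel,
    )
    return mel


def _mel_to_hz(mel: np.ndarray, htk: bool) -> np.ndarray:
    mel = np.asarray(mel, dtype=np.float64)
    if htk:
        return 700.0 * (10.0 ** (mel / 2595.0) - 1.0)
    f_min, f_sp = 0.0, 200.0 / 3
    freq = f_min + f_sp * mel
    min_log_hz = 1000.0
    min_log_mel = (min_log_hz - f_min) / f_sp
    logstep = np.log(6.4) / 27.0
    above = mel >= min_log_mel
    return np.where(
        above, min_log_hz * np.exp(logstep * (mel - min_log_mel)), freq
    )


def mel_filterbank(config: MelConfig) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1).

    Band edges span 0 .. sr/2; Slaney area normalization (each filter scaled
    by 2 / bandwidth) keeps per-band response comparable across frequency.
    """
    n_bins = config.n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, config.sample_rate / 2.0, n_bins)
    mel_edges = np.linspace(
        _hz_to_mel(0.0, config.htk),
        _hz_to_mel(config.sample_rate / 2.0, config.htk),
        config.n_mels + 2,
    )
    hz_edges = _mel_to_hz(mel_edges, config.htk)
    weights = np.zeros((config.n_mels, n_bins))
    for m in range(config.n_mels):
        lower, center, upper = hz_edges[m : m + 3]
        rising = (fft_freqs - lower) / max(center - lower, 1e-12)
        falling = (upper - fft_freqs) / max(upper - center, 1e-12)
        weights[m] = np.maximum(0.0, np.minimum(rising, falling))
        weights[m] *= 2.0 / (upper - lower)  # Slaney area norm
    return weights


def mel_center_frequencies(config: MelConfig) -> np.ndarray:
    """Center frequency (Hz) of each mel band."""
    mel_edges = np.linspace(
        _hz_to_mel(0.0, config.htk),
        _hz_to_mel(config.sample_rate / 2.0, config.htk),
        config.n_mels + 2,
    )
    return _mel_to_hz(mel_edges, config.htk)[1:-1]


def stft_power(wave: np.ndarray, config: MelConfig) -> np.ndarray:
    """Centered STFT power magnitude |X|^2, shape (n_fft//2+1, n_frames)."""
    wave = np.asarray(wave, dtype=np.float64)
    if wave.size == 0:
        raise ValueError("empty waveform")
    pad = config.n_fft // 2
    padded = np.pad(wave, pad, mode="reflect" if wave.size > pad else "constant")
    window = get_window("hann", config.win_length, fftbins=True)
    if config.n_fft > config.win_length:
        window = np.pad(window, (config.n_fft - config.win_length) // 2)
    n_frames = config.n_frames(wave.size)
    hop = config.hop_length
    idx = np.arange(config.n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = padded[idx] * window[None, :]
    spectrum = np.fft.rfft(frames, n=config.n_fft, axis=1)
    return (np.abs(spectrum) ** 2).T


def melspectrogram(
    wave: np.ndarray, config: Optional[MelConfig] = None, source: str = ""
) -> MelSpectrogram:
    """Waveform (at config.sample_rate) -> log-power mel spectrogram."""
    config = config or MelConfig()
    wave = np.asarray(wave, dtype=np.float64)
    if wave.size == 0:
        raise ValueError("empty waveform")
    emphasized = preemphasize(wave, config.preemphasis_alpha)
    power = stft_power(emphasized, config)
    mel_power = mel_filterbank(config) @ power
    values = np.log(np.maximum(mel_power, config.log_floor))
    return MelSpectrogram(values=values, config=config, source=source)


def melspec_cosine_similarity(a: MelSpectrogram, b: MelSpectrogram) -> float:
    """Cosine of the angle between two flattened spectrograms in [-1, 1].

    Mismatched frame counts are cropped to the shorter; zero-norm input is
    rejected.
    """
    va, vb = a.values, b.values
    if va.shape[0] != vb.shape[0]:
        raise ValueError("spectrograms have different mel-band counts")
    n = min(va.shape[1], vb.shape[1])
    x, y = va[:, :n].ravel(), vb[:, :n].ravel()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))
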