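"""Waveform augmentations for training-split samples.

Seven transforms, each length-preserving: Gaussian noise (fixed sigma),
Gaussian noise at a target SNR, gain, polarity inversion, tanh drive
distortion, contiguous time masking, and time stretch/compression (the
stretched signal is center-cropped or zero-padded back to the original
length, since the model needs fixed 2-s input).

Training applies ``compose_random_two``: two distinct transforms drawn
uniformly without replacement, parameters drawn from the configured ranges,
applied in draw order. Test splits never pass through this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

import numpy as np
from scipy.signal import resample_poly


@dataclass(frozen=True)
class AugmentConfig:
    """Parameter ranges for the 2-of-7 composition.

    Defaults are audible but label-preserving for sustained-vowel clips.
    """

    noise_sigma: tuple[float, float] = (0.001, 0.015)
    snr_db: tuple[float, float] = (3.0, 30.0)
    gain_db: tuple[float, float] = (-12.0, 12.0)
    tanh_drive: tuple[float, float] = (1.0, 4.0)
    time_mask_fraction: tuple[float, float] = (0.02, 0.2)
    stretch_rate: tuple[float, float] = (0.8, 1.25)

    def __post_init__(self) -> None:
        for name in (
            "noise_sigma", "snr_db", "gain_db", "tanh_drive",
            "time_mask_fraction", "stretch_rate",
        ):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not (0.0 < self.time_mask_fraction[1] <= 0.5):
            raise ValueError("time_mask_fraction upper bound must be in (0, 0.5]")


def add_gaussian_noise(wave: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add N(0, sigma^2) noise per sample."""
    wave = np.asarray(wave, dtype=np.float64)
    return wave + rng.normal(0.0, sigma, size=wave.shape)


def add_noise_at_snr(wave: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    """Add white noise scaled so 10*log10(P_signal / P_noise) == snr_db."""
    wave = np.asarray(wave, dtype=np.float64)
    p_signal = float(np.mean(wave**2))
    if p_signal == 0.0:
        return wave.copy()
    noise = rng.normal(0.0, 1.0, size=wave.shape)
    p_noise_target = p_signal / (10.0 ** (snr_db / 10.0))
    noise *= np.sqrt(p_noise_target / np.mean(noise**2))
    return wave + noise


def adjust_gain(wave: np.ndarray, gain_db: float) -> np.ndarray:
    """Scale amplitude by 10^(gain_db / 20)."""
    return np.asarray(wave, dtype=np.float64) * (10.0 ** (gain_db / 20.0))


def invert_polarity(wave: np.ndarray) -> np.ndarray:
    return -np.asarray(wave, dtype=np.float64)


def tanh_distort(wave: np.ndarray, drive: float) -> np.ndarray:
    """Soft-clip: tanh(drive*x) / tanh(drive), bounded in [-1, 1]."""
    if drive <= 0:
        raise ValueError("drive must be positive")
    wave = np.asarray(wave, dtype=np.float64)
    return np.tanh(drive * wave) / np.tanh(drive)


def time_mask(wave: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Zero one contiguous interval covering ``fraction`` of the clip."""
    if not (0.0 < fraction <= 0.5):
        raise ValueError("mask fraction must be in (0, 0.5]")
    wave = np.asarray(wave, dtype=np.float64).copy()
    n = wave.shape[0]
    width = max(1, int(round(fraction * n)))
    start = int(rng.integers(0, n - width + 1))
    wave[start : start + width] = 0.0
    return wave


def time_stretch(wave: np.ndarray, rate: float) -> np.ndarray:
    """Stretch (rate < 1) or compress (rate > 1) playback, refit to length.

    Resampling-based: pitch shifts with the rate, which is acceptable for an
    augmentation meant to perturb, not preserve, fine temporal structure.
    Output is center-cropped or zero-padded back to the input length.
    """
    if rate <= 0:
        raise ValueError("stretch rate must be positive")
    wave = np.asarray(wave, dtype=np.float64)
    n = wave.shape[0]
    frac = Fraction(rate).limit_denominator(100)
    stretched = resample_poly(wave, frac.denominator, frac.numerator)
    m = stretched.shape[0]
    if m >= n:
        start = (m - n) // 2
        return stretched[start : start + n]
    pad = n - m
    return np.pad(stretched, (pad // 2, pad - pad // 2))


_TRANSFORM_NAMES = (
    "gaussian_noise",
    "noise_at_snr",
    "gain",
    "polarity",
    "tanh_distort",
    "time_mask",
    "time_stretch",
)


def _apply_named(
    name: str, wave: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    if name == "gaussian_noise":
        return add_gaussian_noise(wave, rng.uniform(*cfg.noise_sigma), rng)
    if name == "noise_at_snr":
        return add_noise_at_snr(wave, rng.uniform(*cfg.snr_db), rng)
    if name == "gain":
        return adjust_gain(wave, rng.uniform(*cfg.gain_db))
    if name == "polarity":
        return invert_polarity(wave)
    if name == "tanh_distort":
        return tanh_distort(wave, rng.uniform(*cfg.tanh_drive))
    if name == "time_mask":
        return time_mask(wave, rng.uniform(*cfg.time_mask_fraction), rng)
    if name == "time_stretch":
        return time_stretch(wave, rng.uniform(*cfg.stretch_rate))
    raise ValueError(f"unknown transform {name!r}")


def compose_random_two(
    wave: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply 2 distinct transforms drawn uniformly without replacement.

    Deterministic given the generator state; output length equals input
    length.
    """
    wave = np.asarray(wave, dtype=np.float64)
    chosen = rng.choice(len(_TRANSFORM_NAMES), size=2, replace=False)
    out = wave
    for i in chosen:
        out = _apply_named(_TRANSFORM_NAMES[i], out, cfg, rng)
    assert out.shape == wave.shape
    return out
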