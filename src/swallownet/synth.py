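"""Synthetic sustained-vowel cohort generator.

Stands in for the study's private clinical recordings: per-subject pre- and
post-swallow /a/ phonations for a normal and an aspiration group. Each vowel
is source-filter synthesized — a glottal pulse train with per-cycle period
perturbation (jitter) and amplitude perturbation (shimmer), spectrally tilted
and passed through three formant resonators, plus white noise scaled to a
harmonics-to-noise (HNR) target.

The class signal lives in the pre-to-post CHANGE: aspiration-group post
recordings receive additive jitter/shimmer increments and an HNR decrement
(``post_delta``), while normal subjects' pre and post draws share parameters.
Baseline voice parameters are matched across groups — the i-th aspiration
subject of a sex reuses the i-th normal subject's baseline draw (with
independent waveform realizations) — so no chance correlation between
baseline voice and group label can masquerade as signal in small cohorts.
This specifically exercises the paired architecture rather than baseline
voice differences.

The generator is a test harness, not a clinical voice simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .audio import RawRecording, write_wav


@dataclass(frozen=True)
class PostDelta:
    """Perturbation added to aspiration-group post-swallow recordings."""

    jitter_pct: float = 2.0
    shimmer_pct: float = 6.0
    hnr_db: float = 10.0  # decrement

    def __post_init__(self) -> None:
        if min(self.jitter_pct, self.shimmer_pct, self.hnr_db) < 0:
            raise ValueError("post_delta increments must be non-negative")


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level generation parameters.

    ``n_per_cell`` subjects are drawn for each (group x sex) cell; the
    default of 10 gives two test subjects per class in every fold of a
    10-fold subject-grouped split, the minimum at which a fold's AUC is not
    a single between-subject comparison. Baseline perturbations approximate
    healthy sustained phonation (jitter ~0.5%, shimmer ~3%, HNR ~25 dB);
    sex-specific f0 ranges cover typical adult speaking pitch.
    """

    n_per_cell: int = 10
    duration_s: float = 5.0
    sample_rate: int = 44_100
    f0_range_male: tuple[float, float] = (100.0, 140.0)
    f0_range_female: tuple[float, float] = (180.0, 240.0)
    jitter_pct: float = 0.5
    shimmer_pct: float = 3.0
    noise_hnr_db: float = 25.0
    formant_freqs: tuple[float, ...] = (800.0, 1200.0, 2500.0)
    formant_bandwidths: tuple[float, ...] = (80.0, 120.0, 160.0)
    post_delta: PostDelta = field(default_factory=PostDelta)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ValueError("jitter/shimmer must be non-negative")
        if self.duration_s < 2.0:
            raise ValueError("duration must be >= 2 s so segmentation yields audio")
        if len(self.formant_freqs) != len(self.formant_bandwidths):
            raise ValueError("one bandwidth per formant required")


def synth_vowel(
    f0: float,
    jitter_pct: float,
    shimmer_pct: float,
    noise_hnr_db: float,
    formants: tuple[float, ...],
    bandwidths: tuple[float, ...],
    duration_s: float,
    rate: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Source-filter synthesis of one sustained /a/ phonation.

    Pulse positions follow T_i = T0 * (1 + N(0, (jitter_pct/100)^2)); pulse
    amplitudes follow 1 + N(0, (shimmer_pct/100)^2). White noise is scaled so
    10*log10(P_harmonic / P_noise) equals ``noise_hnr_db``. Output is
    peak-normalized to 0.9.
    """
    if f0 >= rate / 4:
        raise ValueError(f"f0={f0} too high for sample rate {rate}")
    n = int(round(duration_s * rate))
    t0 = rate / f0  # nominal period in samples

    # glottal pulse train with jittered periods and shimmered amplitudes
    source = np.zeros(n)
    pos = float(rng.uniform(0, t0))
    while pos < n:
        amp = 1.0 + rng.normal(0.0, shimmer_pct / 100.0)
        source[int(pos)] = amp
        period = t0 * (1.0 + rng.normal(0.0, jitter_pct / 100.0))
        pos += max(period, 2.0)

    # -12 dB/oct source tilt (two one-pole low-pass stages)
    tilt = 0.96
    source = lfilter([1.0 - tilt], [1.0, -tilt], source)
    source = lfilter([1.0 - tilt], [1.0, -tilt], source)

    harmonic = source
    for freq, bw in zip(formants, bandwidths):
        r = np.exp(-np.pi * bw / rate)
        theta = 2.0 * np.pi * freq / rate
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        b = [1.0 - r]
        harmonic = lfilter(b, a, harmonic)

    p_harm = float(np.mean(harmonic**2))
    noise = rng.normal(0.0, 1.0, size=n)
    p_noise_target = p_harm / (10.0 ** (noise_hnr_db / 10.0))
    noise *= np.sqrt(p_noise_target / np.mean(noise**2))

    wave = harmonic + noise
    peak = np.max(np.abs(wave))
    return wave * (0.9 / peak) if peak > 0 else wave


def estimate_f0(wave: np.ndarray, rate: int, fmin: float = 60.0, fmax: float = 400.0) -> float:
    """Autocorrelation pitch estimate (Hz) over the plausible-lag window."""
    wave = np.asarray(wave, dtype=np.float64)
    wave = wave - wave.mean()
    ac = np.correlate(wave, wave, mode="full")[len(wave) - 1 :]
    ac /= ac[0]
    lag_min = int(rate / fmax)
    lag_max = min(int(rate / fmin), len(ac) - 1)
    lag = lag_min + int(np.argmax(ac[lag_min:lag_max]))
    return rate / lag


def estimate_hnr(wave: np.ndarray, rate: int, fmin: float = 60.0, fmax: float = 400.0) -> float:
    """Autocorrelation HNR (dB): 10*log10(r_max / (1 - r_max)) at the pitch lag."""
    wave = np.asarray(wave, dtype=np.float64)
    wave = wave - wave.mean()
    ac = np.correlate(wave, wave, mode="full")[len(wave) - 1 :]
    ac /= ac[0]
    lag_min = int(rate / fmax)
    lag_max = min(int(rate / fmin), len(ac) - 1)
    r_max = float(np.max(ac[lag_min:lag_max]))
    r_max = min(r_max, 1.0 - 1e-9)
    return 10.0 * np.log10(r_max / (1.0 - r_max))


def _subject_params(cfg: SynthConfig, sex: str, rng: np.random.Generator) -> dict:
    lo, hi = cfg.f0_range_male if sex == "male" else cfg.f0_range_female
    return {
        "f0": float(rng.uniform(lo, hi)),
        "jitter_pct": cfg.jitter_pct * float(rng.uniform(0.7, 1.3)),
        "shimmer_pct": cfg.shimmer_pct * float(rng.uniform(0.7, 1.3)),
        "noise_hnr_db": cfg.noise_hnr_db + float(rng.uniform(-2.0, 2.0)),
    }


def twin_key(subject_id: str) -> str:
    """Matched-pair key: a normal subject and the aspiration subject sharing
    its baseline parameter draw map to the same key (e.g. M003N / M003A ->
    M003). Matched pairs must be placed in the same cross-validation fold,
    otherwise a test subject's opposite-label twin sits in training and the
    model scores the test subject like its twin."""
    return subject_id[:-1]


def generate_cohort_recordings(cfg: SynthConfig) -> list[RawRecording]:
    """Generate one pre and one post RawRecording per synthetic subject.

    Subjects are laid out over the (group x sex) grid with ``n_per_cell``
    subjects per cell. Aspiration-group post recordings receive the
    ``post_delta`` perturbations; all other recordings use the subject's
    baseline parameters (with independent noise draws).
    """
    rng = np.random.default_rng(cfg.seed)
    # one baseline parameter set per (sex, slot), shared by both groups:
    # the class signal must live in the pre->post change alone
    baselines = {
        sex: [_subject_params(cfg, sex, rng) for _ in range(cfg.n_per_cell)]
        for sex in ("male", "female")
    }
    recordings: list[RawRecording] = []
    for group in ("normal", "aspiration"):
        for sex in ("male", "female"):
            for slot in range(cfg.n_per_cell):
                subject_id = (
                    f"{'M' if sex == 'male' else 'F'}{slot:03d}"
                    f"{'N' if group == 'normal' else 'A'}"
                )
                params = baselines[sex][slot]
                for phase in ("pre", "post"):
                    p = dict(params)
                    if group == "aspiration" and phase == "post":
                        p["jitter_pct"] += cfg.post_delta.jitter_pct
                        p["shimmer_pct"] += cfg.post_delta.shimmer_pct
                        p["noise_hnr_db"] -= cfg.post_delta.hnr_db
                    wave = synth_vowel(
                        f0=p["f0"],
                        jitter_pct=p["jitter_pct"],
                        shimmer_pct=p["shimmer_pct"],
                        noise_hnr_db=p["noise_hnr_db"],
                        formants=cfg.formant_freqs,
                        bandwidths=cfg.formant_bandwidths,
                        duration_s=cfg.duration_s,
                        rate=cfg.sample_rate,
                        rng=rng,
                    )
                    recordings.append(
                        RawRecording(
                            subject_id=subject_id,
                            phase=phase,
                            group_label=group,
                            sex=sex,
                            waveform=wave,
                            sample_rate=cfg.sample_rate,
                            substance="water",
                            device="synthetic",
                        )
                    )
    return recordings


def generate_cohort(cfg: SynthConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write the cohort as wav files plus a manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in generate_cohort_recordings(cfg):
        name = f"{rec.subject_id}_{rec.phase}.wav"
        write_wav(out_dir / name, rec.waveform, rec.sample_rate)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "phase": rec.phase,
                "group_label": rec.group_label,
                "sex": rec.sex,
                "substance": rec.substance,
                "device": rec.device,
                "path": name,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
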