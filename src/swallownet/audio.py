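"""Standardization of raw sustained-vowel recordings.

Raw captures arrive as ~5 s "ah~" phonations in heterogeneous formats
(mono/stereo, various rates, wav/mp3/m4a). This module normalizes them into
the pipeline's working unit: mono, rate-normalized, exactly-2-s segments,
optionally transcoded to a compact byte payload for storage.

The stages are: endpoint trimming (manual boundaries or an energy-threshold
auto-trimmer), stereo splitting, band-limited resampling, fixed-length
segmentation, and encoding. Segmentation uses non-overlapping consecutive
windows from sample 0 and discards the sub-length tail.
"""

from __future__ import annotations

import io
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

PHASES = ("pre", "post")
GROUPS = ("normal", "aspiration")
SEXES = ("male", "female")
SUBSTANCES = ("water", "YP", "SF", "SBD", "FT3", "LF")

MANIFEST_COLUMNS = [
    "subject_id",
    "phase",
    "group_label",
    "sex",
    "substance",
    "device",
    "path",
]


class EncoderUnavailableError(RuntimeError):
    """No external mp3/m4a codec (ffmpeg or lame) is installed."""


class DecodeError(ValueError):
    """Byte payload could not be decoded back to audio."""


@dataclass
class RawRecording:
    """One subject-phase audio capture with study metadata.

    ``waveform`` is float in [-1, 1]; mono recordings are 1-D arrays of
    shape (n,), stereo recordings are (n, 2).
    """

    subject_id: str
    phase: str
    group_label: str
    sex: str
    waveform: np.ndarray
    sample_rate: int
    substance: Optional[str] = None
    device: Optional[str] = None

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.group_label not in GROUPS:
            raise ValueError(f"group_label must be one of {GROUPS}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.waveform.size < 1:
            raise ValueError("waveform must contain at least one sample")
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform contains non-finite samples")
        if self.waveform.ndim not in (1, 2):
            raise ValueError("waveform must be 1-D (mono) or 2-D (n, 2) (stereo)")
        if self.waveform.ndim == 2 and self.waveform.shape[1] != 2:
            raise ValueError("stereo waveform must have shape (n, 2)")

    @property
    def channels(self) -> int:
        return 1 if self.waveform.ndim == 1 else self.waveform.shape[1]

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class AudioSegment:
    """A mono, fixed-duration slice of a standardized recording."""

    subject_id: str
    phase: str
    segment_index: int
    waveform: np.ndarray
    target_rate: int
    duration_s: float = 2.0
    group_label: Optional[str] = None
    sex: Optional[str] = None
    substance: Optional[str] = None

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        expected = int(round(self.duration_s * self.target_rate))
        if self.waveform.ndim != 1:
            raise ValueError("AudioSegment must be mono (1-D)")
        if self.waveform.shape[0] != expected:
            raise ValueError(
                f"segment length {self.waveform.shape[0]} != "
                f"duration_s*target_rate = {expected}"
            )
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("segment contains non-finite samples")


@dataclass
class EncodedClip:
    """Encoded byte payload for one AudioSegment.

    ``codec`` is "wav" (RIFF PCM-16, always available) or "mp3"
    (CBR 64 kbps via an external codec when one is installed).
    """

    payload: bytes
    codec: str
    sample_rate: int
    channels: int = 1
    bitrate_kbps: Optional[int] = None
    source: str = ""


# ---------------------------------------------------------------------------
# stage 1: endpoint trimming


def trim_endpoints(rec: RawRecording, lead_s: float, trail_s: float) -> RawRecording:
    """Remove ``lead_s`` seconds from the head and ``trail_s`` from the tail.

    Used to cut pre/post-phonation room noise at the recording endpoints.
    """
    if lead_s < 0 or trail_s < 0:
        raise ValueError("trim amounts must be non-negative")
    n = rec.n_samples
    head = int(round(lead_s * rec.sample_rate))
    tail = int(round(trail_s * rec.sample_rate))
    if head + tail >= n:
        raise ValueError(
            f"trim of {lead_s}+{trail_s}s leaves no samples in a "
            f"{rec.duration_s:.3f}s recording"
        )
    sliced = rec.waveform[head : n - tail if tail else n]
    return replace(rec, waveform=sliced)


def auto_trim(
    rec: RawRecording, rms_fraction: float = 0.01, frame_s: float = 0.02
) -> RawRecording:
    """Energy-threshold endpoint trimmer.

    Frames whose RMS falls below ``rms_fraction`` of the recording's peak
    frame RMS are cut from the head and tail. Stand-in for the study's
    manual endpoint denoising.
    """
    mono = rec.waveform if rec.channels == 1 else rec.waveform.mean(axis=1)
    frame = max(1, int(round(frame_s * rec.sample_rate)))
    n_frames = len(mono) // frame
    if n_frames == 0:
        return rec
    frames = mono[: n_frames * frame].reshape(n_frames, frame)
    rms = np.sqrt((frames**2).mean(axis=1))
    thresh = rms_fraction * rms.max()
    active = np.nonzero(rms >= thresh)[0]
    if active.size == 0:
        return rec
    head = active[0] * frame
    tail_end = min(rec.n_samples, (active[-1] + 1) * frame)
    return replace(rec, waveform=rec.waveform[head:tail_end])


# ---------------------------------------------------------------------------
# stage 2: channel and rate normalization


def split_stereo(rec: RawRecording) -> tuple[RawRecording, RawRecording]:
    """Split a stereo recording into (left, right) mono recordings."""
    if rec.channels != 2:
        raise ValueError("split_stereo requires stereo input; pass mono through")
    left = replace(
        rec,
        waveform=rec.waveform[:, 0].copy(),
        device=f"{rec.device or ''}:L".lstrip(":"),
    )
    right = replace(
        rec,
        waveform=rec.waveform[:, 1].copy(),
        device=f"{rec.device or ''}:R".lstrip(":"),
    )
    return left, right


def to_mono(rec: RawRecording) -> RawRecording:
    """Average channels to mono (identity for mono input)."""
    if rec.channels == 1:
        return rec
    return replace(rec, waveform=rec.waveform.mean(axis=1))


def resample(wave: np.ndarray, from_rate: int, to_rate: int) -> np.ndarray:
    """Band-limited polyphase resampling.

    Output length is round(len(wave) * to_rate / from_rate); identical rates
    return the input unchanged.
    """
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("sample rates must be positive")
    wave = np.asarray(wave, dtype=np.float64)
    if from_rate == to_rate:
        return wave
    frac = Fraction(to_rate, from_rate)
    out = resample_poly(wave, frac.numerator, frac.denominator)
    target_len = int(round(len(wave) * to_rate / from_rate))
    if len(out) > target_len:
        out = out[:target_len]
    elif len(out) < target_len:
        out = np.pad(out, (0, target_len - len(out)))
    return out


def resample_recording(rec: RawRecording, to_rate: int) -> RawRecording:
    if rec.channels != 1:
        raise ValueError("resample_recording expects mono input")
    return replace(
        rec, waveform=resample(rec.waveform, rec.sample_rate, to_rate),
        sample_rate=to_rate,
    )


# ---------------------------------------------------------------------------
# stage 3: fixed-length segmentation and encoding


def segment_fixed(rec: RawRecording, seg_len_s: float = 2.0) -> list[AudioSegment]:
    """Cut a mono recording into consecutive non-overlapping windows.

    Windows start at sample 0; the trailing remainder shorter than
    ``seg_len_s`` is discarded. Recordings shorter than one window yield an
    empty list and a logged warning.
    """
    if rec.channels != 1:
        raise ValueError("segment_fixed requires mono input")
    seg_len = int(round(seg_len_s * rec.sample_rate))
    n_segments = rec.n_samples // seg_len
    if n_segments == 0:
        logger.warning(
            "recording %s/%s is %.3fs, shorter than the %.1fs window; skipped",
            rec.subject_id, rec.phase, rec.duration_s, seg_len_s,
        )
        return []
    return [
        AudioSegment(
            subject_id=rec.subject_id,
            phase=rec.phase,
            segment_index=i,
            waveform=rec.waveform[i * seg_len : (i + 1) * seg_len].copy(),
            target_rate=rec.sample_rate,
            duration_s=seg_len_s,
            group_label=rec.group_label,
            sex=rec.sex,
            substance=rec.substance,
        )
        for i in range(n_segments)
    ]


def _find_mp3_encoder() -> Optional[str]:
    for tool in ("ffmpeg", "lame"):
        if shutil.which(tool):
            return tool
    return None


def encode_wav(seg: AudioSegment) -> EncodedClip:
    """Encode a segment as RIFF/WAV PCM-16 bytes (always available)."""
    pcm = np.clip(seg.waveform, -1.0, 1.0)
    data = (pcm * 32767.0).astype(np.int16)
    buf = io.BytesIO()
    wavfile.write(buf, seg.target_rate, data)
    return EncodedClip(
        payload=buf.getvalue(),
        codec="wav",
        sample_rate=seg.target_rate,
        channels=1,
        source=f"{seg.subject_id}/{seg.phase}/{seg.segment_index}",
    )


def transcode_mp3(seg: AudioSegment, bitrate_kbps: int = 64) -> EncodedClip:
    """Encode a segment as CBR mono mp3 via an external codec.

    Raises EncoderUnavailableError when neither ffmpeg nor lame is on PATH.
    """
    tool = _find_mp3_encoder()
    if tool is None:
        raise EncoderUnavailableError(
            "mp3 encoding requires ffmpeg or lame on PATH; neither was found. "
            "Use encode_wav for a codec-free payload."
        )
    wav_clip = encode_wav(seg)
    with tempfile.TemporaryDirectory() as tmp:
        wav_path = Path(tmp) / "in.wav"
        mp3_path = Path(tmp) / "out.mp3"
        wav_path.write_bytes(wav_clip.payload)
        if tool == "ffmpeg":
            cmd = ["ffmpeg", "-y", "-loglevel", "error", "-i", str(wav_path),
                   "-ac", "1", "-b:a", f"{bitrate_kbps}k", str(mp3_path)]
        else:
            cmd = ["lame", "--quiet", "-m", "m", "-b", str(bitrate_kbps),
                   str(wav_path), str(mp3_path)]
        subprocess.run(cmd, check=True)
        payload = mp3_path.read_bytes()
    return EncodedClip(
        payload=payload,
        codec="mp3",
        sample_rate=seg.target_rate,
        channels=1,
        bitrate_kbps=bitrate_kbps,
        source=f"{seg.subject_id}/{seg.phase}/{seg.segment_index}",
    )


def encode_clip(seg: AudioSegment, codec: str = "wav") -> EncodedClip:
    """Encode with the requested codec ("wav" or "mp3")."""
    if codec == "wav":
        return encode_wav(seg)
    if codec == "mp3":
        return transcode_mp3(seg)
    raise ValueError(f"unknown codec {codec!r}")


def decode_clip(clip: EncodedClip, target_rate: Optional[int] = None) -> np.ndarray:
    """Decode a payload back to a mono float waveform at ``target_rate``.

    mp3 payloads need an external decoder; codec delay/padding is trimmed so
    the nominal duration is restored within one hop of the original.
    """
    if clip.codec == "wav":
        try:
            rate, data = wavfile.read(io.BytesIO(clip.payload))
        except Exception as exc:  # corrupt RIFF header or truncation
            raise DecodeError(f"invalid wav payload: {exc}") from exc
        wave = data.astype(np.float64) / 32767.0
        if wave.ndim == 2:
            wave = wave.mean(axis=1)
    elif clip.codec == "mp3":
        if shutil.which("ffmpeg") is None:
            raise EncoderUnavailableError("mp3 decoding requires ffmpeg on PATH")
        with tempfile.TemporaryDirectory() as tmp:
            mp3_path = Path(tmp) / "in.mp3"
            wav_path = Path(tmp) / "out.wav"
            mp3_path.write_bytes(clip.payload)
            try:
                subprocess.run(
                    ["ffmpeg", "-y", "-loglevel", "error", "-i", str(mp3_path),
                     "-ac", "1", str(wav_path)],
                    check=True,
                )
                rate, data = wavfile.read(wav_path)
            except Exception as exc:
                raise DecodeError(f"mp3 decode failed: {exc}") from exc
        wave = data.astype(np.float64) / 32767.0
        # mp3 framing pads both ends; keep the centered nominal-length slice
        nominal = int(round(len(wave) / rate * clip.sample_rate))
        if rate == clip.sample_rate and len(wave) > nominal:
            excess = len(wave) - nominal
            wave = wave[excess // 2 : excess // 2 + nominal]
    else:
        raise ValueError(f"unknown codec {clip.codec!r}")
    if not np.all(np.isfinite(wave)):
        raise DecodeError("decoded waveform contains non-finite samples")
    if target_rate is not None and target_rate != rate:
        wave = resample(wave, rate, target_rate)
    return wave


def decode_mp3(clip: EncodedClip, target_rate: int) -> np.ndarray:
    """Decode an mp3 (or wav) payload to a mono waveform at ``target_rate``."""
    return decode_clip(clip, target_rate=target_rate)


# ---------------------------------------------------------------------------
# file + manifest I/O


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM wav file to float64 in [-1, 1]; stereo stays (n, 2)."""
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        wave = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        wave = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        wave = (data.astype(np.float64) - 128.0) / 127.0
    else:
        wave = data.astype(np.float64)
    return wave, int(rate)


def write_wav(path: str | Path, wave: np.ndarray, rate: int) -> None:
    data = (np.clip(np.asarray(wave), -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(path, rate, data)


def load_recording(row: dict, base_dir: str | Path = ".") -> RawRecording:
    """Load one manifest row (audio file + metadata) as a RawRecording."""
    path = Path(base_dir) / row["path"]
    suffix = path.suffix.lower()
    if suffix == ".wav":
        wave, rate = read_wav(path)
    elif suffix in (".mp3", ".m4a"):
        if shutil.which("ffmpeg") is None:
            raise EncoderUnavailableError(
                f"reading {suffix} files requires ffmpeg on PATH"
            )
        with tempfile.TemporaryDirectory() as tmp:
            out = Path(tmp) / "out.wav"
            subprocess.run(
                ["ffmpeg", "-y", "-loglevel", "error", "-i", str(path), str(out)],
                check=True,
            )
            wave, rate = read_wav(out)
    else:
        raise ValueError(f"unsupported audio format {suffix!r}")

    def _opt(key: str) -> Optional[str]:
        val = row.get(key)
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            return None
        return str(val)

    return RawRecording(
        subject_id=str(row["subject_id"]),
        phase=str(row["phase"]),
        group_label=str(row["group_label"]),
        sex=str(row["sex"]),
        waveform=wave,
        sample_rate=rate,
        substance=_opt("substance"),
        device=_opt("device"),
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the cohort manifest CSV and validate its columns."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def standardize_recording(
    rec: RawRecording,
    target_rate: int = 32_000,
    seg_len_s: float = 2.0,
    lead_s: float = 0.0,
    trail_s: float = 0.0,
    auto: bool = False,
) -> list[AudioSegment]:
    """Run the full standardization chain on one raw recording.

    trim -> split stereo (each channel processed independently) -> resample
    to ``target_rate`` -> cut into ``seg_len_s`` windows. Stereo recordings
    contribute segments from both channels, with a continuing segment index.
    """
    if lead_s or trail_s:
        rec = trim_endpoints(rec, lead_s, trail_s)
    if auto:
        rec = auto_trim(rec)
    monos = list(split_stereo(rec)) if rec.channels == 2 else [rec]
    segments: list[AudioSegment] = []
    for mono in monos:
        mono = resample_recording(mono, target_rate)
        for seg in segment_fixed(mono, seg_len_s):
            seg.segment_index = len(segments)
            segments.append(seg)
    return segments
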