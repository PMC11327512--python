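"""Audio standardization: trimming, stereo handling, resampling,
fixed-length segmentation and payload round-trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swallownet.audio import (
    AudioSegment,
    EncoderUnavailableError,
    DecodeError,
    EncodedClip,
    RawRecording,
    _find_mp3_encoder,
    decode_clip,
    encode_wav,
    resample,
    segment_fixed,
    split_stereo,
    standardize_recording,
    transcode_mp3,
    trim_endpoints,
)


def _rec(wave, rate=32_000, **kw):
    defaults = dict(
        subject_id="S1", phase="pre", group_label="normal", sex="male",
        waveform=wave, sample_rate=rate,
    )
    defaults.update(kw)
    return RawRecording(**defaults)


class TestTrim:
    def test_lead_trail_removed(self):
        rec = _rec(np.arange(5 * 1000) / 5000.0, rate=1000)
        out = trim_endpoints(rec, 0.3, 0.2)
        assert out.n_samples == 4500
        np.testing.assert_array_equal(out.waveform, rec.waveform[300:4800])

    def test_zero_trim_is_identity(self):
        rec = _rec(np.linspace(-1, 1, 800), rate=400)
        out = trim_endpoints(rec, 0.0, 0.0)
        np.testing.assert_array_equal(out.waveform, rec.waveform)

    def test_empty_slice_rejected(self):
        rec = _rec(np.ones(1000) * 0.1, rate=1000)
        with pytest.raises(ValueError, match="leaves no samples"):
            trim_endpoints(rec, 0.6, 0.6)


class TestStereo:
    def test_channel_separation(self):
        t = np.arange(1000) / 1000.0
        sine = np.sin(2 * np.pi * 50 * t)
        stereo = np.stack([sine, np.zeros_like(sine)], axis=1)
        left, right = split_stereo(_rec(stereo))
        np.testing.assert_array_equal(left.waveform, sine)
        np.testing.assert_array_equal(right.waveform, np.zeros(1000))
        assert left.channels == right.channels == 1

    def test_identical_channels_give_identical_monos(self):
        sig = np.linspace(0, 0.5, 600)
        left, right = split_stereo(_rec(np.stack([sig, sig], axis=1)))
        np.testing.assert_array_equal(left.waveform, right.waveform)

    def test_mono_input_rejected(self):
        with pytest.raises(ValueError, match="pass mono through"):
            split_stereo(_rec(np.ones(100) * 0.1))


class TestResample:
    def test_one_second_stays_one_second(self):
        wave = np.random.default_rng(0).normal(size=44_100)
        out = resample(wave, 44_100, 32_000)
        assert len(out) == 32_000

    def test_identity_for_equal_rates(self):
        wave = np.random.default_rng(1).normal(size=5000)
        np.testing.assert_array_equal(resample(wave, 16_000, 16_000), wave)

    def test_tone_peak_preserved(self):
        # FFT-peak oracle: a 440-Hz tone must stay at 440 Hz after 44.1->32 kHz
        t = np.arange(44_100) / 44_100
        tone = np.sin(2 * np.pi * 440.0 * t)
        out = resample(tone, 44_100, 32_000)
        spectrum = np.abs(np.fft.rfft(out))
        peak_hz = np.argmax(spectrum) * 32_000 / len(out)
        assert abs(peak_hz - 440.0) <= 32_000 / len(out)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            resample(np.ones(10), 0, 100)

    @given(st.integers(1000, 50_000), st.integers(1000, 50_000))
    def test_length_law(self, from_rate, to_rate):
        wave = np.zeros(3217)
        out = resample(wave, from_rate, to_rate)
        assert len(out) == int(round(3217 * to_rate / from_rate))


class TestSegmentation:
    def test_five_seconds_give_two_segments(self):
        rec = _rec(np.random.default_rng(2).normal(size=5 * 32_000) * 0.1)
        segs = segment_fixed(rec, 2.0)
        assert len(segs) == 2
        assert all(len(s.waveform) == 64_000 for s in segs)

    def test_short_recording_yields_empty(self, caplog):
        rec = _rec(np.ones(int(1.5 * 32_000)) * 0.1)
        with caplog.at_level("WARNING"):
            segs = segment_fixed(rec, 2.0)
        assert segs == []
        assert "shorter" in caplog.text

    def test_partition_property(self):
        # concatenating the segments reproduces the input prefix exactly
        wave = np.random.default_rng(3).normal(size=4 * 32_000) * 0.1
        segs = segment_fixed(_rec(wave), 2.0)
        assert len(segs) == 2
        np.testing.assert_array_equal(
            np.concatenate([s.waveform for s in segs]), wave
        )

    def test_metadata_propagates(self):
        rec = _rec(
            np.ones(2 * 32_000) * 0.1, group_label="aspiration", sex="female",
            substance="YP",
        )
        (seg,) = segment_fixed(rec, 2.0)
        assert (seg.group_label, seg.sex, seg.substance) == ("aspiration", "female", "YP")


class TestPayloads:
    def _segment(self, wave):
        return AudioSegment(
            subject_id="S1", phase="pre", segment_index=0,
            waveform=wave, target_rate=32_000,
        )

    def test_wav_round_trip_is_faithful(self, tone_2s_32k):
        clip = encode_wav(self._segment(tone_2s_32k))
        back = decode_clip(clip)
        assert len(back) == 64_000
        corr = np.corrcoef(back, tone_2s_32k)[0, 1]
        assert corr > 0.999

    def test_silence_round_trip(self):
        clip = encode_wav(self._segment(np.zeros(64_000)))
        assert np.max(np.abs(decode_clip(clip))) < 1e-3

    def test_decoded_range_contract(self, tone_2s_32k):
        back = decode_clip(encode_wav(self._segment(tone_2s_32k * 1.5)))
        assert np.all(np.abs(back) <= 1.0)
        assert np.all(np.isfinite(back))

    def test_corrupt_payload_rejected(self):
        clip = EncodedClip(payload=b"not audio", codec="wav", sample_rate=32_000)
        with pytest.raises(DecodeError):
            decode_clip(clip)

    def test_decode_resamples_to_target_rate(self, tone_2s_32k):
        back = decode_clip(encode_wav(self._segment(tone_2s_32k)), target_rate=16_000)
        assert len(back) == 32_000

    @pytest.mark.skipif(
        _find_mp3_encoder() is not None, reason="an mp3 codec is installed"
    )
    def test_mp3_without_codec_raises_environment_error(self, tone_2s_32k):
        with pytest.raises(EncoderUnavailableError, match="ffmpeg or lame"):
            transcode_mp3(self._segment(tone_2s_32k))

    @pytest.mark.skipif(
        _find_mp3_encoder() is None, reason="no mp3 codec installed"
    )
    def test_mp3_round_trip(self, tone_2s_32k):
        clip = transcode_mp3(self._segment(tone_2s_32k))
        assert clip.bitrate_kbps == 64
        back = decode_clip(clip, target_rate=32_000)
        assert abs(len(back) - 64_000) <= 0.05 * 32_000


class TestStandardizeChain:
    def test_stereo_five_second_recording(self):
        rng = np.random.default_rng(4)
        stereo = rng.normal(size=(5 * 44_100, 2)) * 0.1
        rec = _rec(stereo, rate=44_100)
        segs = standardize_recording(rec, target_rate=32_000, seg_len_s=2.0)
        # each channel gives floor(5/2) = 2 segments
        assert len(segs) == 4
        assert all(len(s.waveform) == 64_000 for s in segs)
        assert [s.segment_index for s in segs] == [0, 1, 2, 3]
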