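"""Preprocessing chain: EDF round-trips, filters, resampling, scaling."""

import numpy as np
import pytest

from somnoseg import (Channel, ContractError, FormatError, PsgPreprocessor,
                      PsgRecord, ScoredRegion, bandpass, derive_channel,
                      normalize, read_edf, resample_to_128, robust_clip,
                      trim_to_scored, write_edf)
from somnoseg.signal_io import (load_record_hdf5, read_scored_region,
                                save_record_hdf5)


def _sine(freq, fs, dur, amp=50.0):
    t = np.arange(int(fs * dur)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _spectral_peak_hz(x, fs):
    spec = np.abs(np.fft.rfft(x))
    return np.fft.rfftfreq(x.size, 1 / fs)[np.argmax(spec)]


class TestEdfRoundTrip:
    def test_two_channel_roundtrip(self, tmp_path, rng):
        rec = PsgRecord((
            Channel("C4-M1", rng.normal(0, 30, 256 * 60), 256.0),
            Channel("E1-FPz", rng.normal(0, 30, 256 * 60), 256.0),
        ))
        path = tmp_path / "t.edf"
        write_edf(rec, path)
        back = read_edf(path)
        assert len(back.channels) == 2
        assert all(c.samples.size == 15360 for c in back.channels)
        for orig, rt in zip(rec.channels, back.channels):
            tol = 2 * np.max(np.abs(orig.samples)) / 32767  # 16-bit quantization
            assert np.allclose(orig.samples, rt.samples, atol=tol)

    def test_zero_channel_content_preserved(self, tmp_path):
        rec = PsgRecord((Channel("flat", np.zeros(1280), 128.0),))
        path = tmp_path / "z.edf"
        write_edf(rec, path)
        back = read_edf(path)
        assert back.channels[0].samples.size == 1280
        assert np.allclose(back.channels[0].samples, 0.0, atol=1e-6)

    def test_truncated_file_rejected(self, tmp_path, rng):
        rec = PsgRecord((Channel("a", rng.normal(0, 10, 1280), 128.0),))
        path = tmp_path / "trunc.edf"
        write_edf(rec, path)
        path.write_bytes(path.read_bytes()[:100])  # cut inside the header
        with pytest.raises((FormatError, IOError)):
            read_edf(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            read_edf(tmp_path / "nope.edf")


class TestDeriveChannel:
    def test_self_reference_is_zero(self, rng):
        rec = PsgRecord((Channel("a", rng.normal(size=100), 10.0),))
        assert np.allclose(derive_channel(rec, "a", "a").samples, 0.0)

    def test_arithmetic(self):
        rec = PsgRecord((
            Channel("act", [1.0, 2.0, 3.0], 1.0),
            Channel("ref", [0.0, 1.0, 1.0], 1.0),
        ))
        assert np.array_equal(derive_channel(rec, "act", "ref").samples,
                              [1.0, 1.0, 2.0])

    def test_matches_elementwise_subtraction(self, rng):
        a, b = rng.normal(size=500), rng.normal(size=500)
        rec = PsgRecord((Channel("x", a, 50.0), Channel("y", b, 50.0)))
        assert np.array_equal(derive_channel(rec, "x", "y").samples, a - b)

    def test_fs_mismatch_and_missing(self):
        rec = PsgRecord((Channel("x", np.zeros(100), 10.0),
                         Channel("y", np.zeros(200), 20.0)))
        with pytest.raises(ContractError):
            derive_channel(rec, "x", "y")
        with pytest.raises(KeyError):
            derive_channel(rec, "x", "zz")


class TestBandpass:
    def test_passband_tone_preserved(self):
        ch = Channel("s", _sine(10, 128, 30), 128.0)
        out = bandpass(ch)
        assert _spectral_peak_hz(out.samples, 128) == pytest.approx(10, abs=0.1)
        ratio = np.max(np.abs(np.fft.rfft(out.samples))) / \
            np.max(np.abs(np.fft.rfft(ch.samples)))
        assert ratio >= 0.9

    def test_stopband_tone_attenuated(self):
        ch = Channel("s", _sine(50, 256, 30), 256.0)
        out = bandpass(ch)
        rms = lambda x: np.sqrt(np.mean(x ** 2))
        assert rms(out.samples) < 0.1 * rms(ch.samples)

    def test_zero_in_zero_out_and_length(self, rng):
        ch = Channel("z", np.zeros(1000), 128.0)
        assert np.allclose(bandpass(ch).samples, 0.0)
        ch2 = Channel("r", rng.normal(size=777), 128.0)
        assert bandpass(ch2).samples.size == 777

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ContractError):
            bandpass(Channel("s", np.zeros(100), 60.0), high_hz=35)


class TestResample:
    def test_identity_at_target_rate(self, rng):
        ch = Channel("s", rng.normal(size=1280), 128.0)
        out = resample_to_128(ch)
        assert np.array_equal(out.samples, ch.samples)

    def test_halving_preserves_tone(self):
        out = resample_to_128(Channel("s", _sine(10, 256, 30), 256.0))
        assert out.samples.size == 3840
        assert out.fs == 128.0
        assert _spectral_peak_hz(out.samples, 128) == pytest.approx(10, abs=0.1)

    def test_length_arithmetic_from_512(self, rng):
        out = resample_to_128(Channel("s", rng.normal(size=512 * 60), 512.0))
        assert out.samples.size == 128 * 60

    def test_idempotent_once_at_target(self, rng):
        once = resample_to_128(Channel("s", rng.normal(size=256 * 4), 256.0))
        twice = resample_to_128(once)
        assert np.array_equal(once.samples, twice.samples)


class TestRobustClip:
    def test_normal_noise_untouched_at_default_k(self, rng):
        ch = Channel("n", rng.standard_normal(10000), 100.0)
        assert np.array_equal(robust_clip(ch).samples, ch.samples)

    def test_outlier_clipped_to_hand_computed_bound(self):
        # q1=1, median=2, q3=3 -> IQR=2; k=2 clips to [-2, 6]
        ch = Channel("o", [0.0, 1.0, 2.0, 3.0, 1000.0], 1.0)
        out = robust_clip(ch, k=2)
        assert np.array_equal(out.samples, [0.0, 1.0, 2.0, 3.0, 6.0])

    def test_zero_iqr_passthrough(self):
        ch = Channel("c", [0.0, 0.0, 0.0, 0.0, 1000.0], 1.0)
        assert np.array_equal(robust_clip(ch, k=2).samples, ch.samples)
        const = Channel("k", np.full(10, 7.0), 1.0)
        assert np.array_equal(robust_clip(const).samples, const.samples)

    def test_never_increases_peak(self, rng):
        for _ in range(20):
            x = rng.standard_t(df=2, size=500) * 10
            out = robust_clip(Channel("t", x, 1.0), k=3)
            assert np.max(np.abs(out.samples)) <= np.max(np.abs(x)) + 1e-12


class TestNormalize:
    def test_constant_becomes_zero(self):
        assert np.allclose(normalize(Channel("c", np.full(10, 5.0), 1.0)).samples, 0)

    def test_symmetric_median_preserved(self):
        out = normalize(Channel("s", [-1.0, 0.0, 1.0], 1.0))
        assert out.samples[1] == 0.0

    def test_output_statistics(self, rng):
        out = normalize(Channel("r", rng.normal(3, 7, 5001), 1.0))
        assert abs(np.median(out.samples)) < 1e-9
        q1, q3 = np.percentile(out.samples, [25, 75])
        assert abs((q3 - q1) - 1.0) < 1e-9


class TestTrim:
    def test_full_region_identity(self, rng):
        rec = PsgRecord((Channel("a", rng.normal(size=1000), 10.0),))
        out = trim_to_scored(rec, ScoredRegion(0, 100))
        assert np.array_equal(out.channels[0].samples, rec.channels[0].samples)
        assert out.start_offset_s == 0.0

    def test_interior_region(self, rng):
        rec = PsgRecord((Channel("a", rng.normal(size=1000), 10.0),))
        out = trim_to_scored(rec, ScoredRegion(10, 90))
        assert out.channels[0].samples.size == 800
        assert out.start_offset_s == 10.0
        assert out.duration_s == pytest.approx(80.0)

    def test_region_outside_recording_rejected(self, rng):
        rec = PsgRecord((Channel("a", rng.normal(size=100), 10.0),))
        with pytest.raises(ContractError):
            trim_to_scored(rec, ScoredRegion(5, 20))


class TestChainAndPersistence:
    def test_chain_is_deterministic(self, rng):
        x = rng.normal(0, 30, 256 * 20)
        rec = PsgRecord((Channel("C4", x.copy(), 256.0),
                         Channel("E1", x[::-1].copy(), 256.0)))
        pre = PsgPreprocessor()
        out1 = pre.transform_record(rec)
        out2 = pre.transform_record(rec)
        for c1, c2 in zip(out1.channels, out2.channels):
            assert np.array_equal(c1.samples, c2.samples)
            assert c1.fs == 128.0

    def test_hdf5_roundtrip(self, tmp_path, rng):
        rec = PsgRecord((Channel("a", rng.normal(size=256), 128.0),), 42.0)
        save_record_hdf5(rec, tmp_path / "r.h5")
        back = load_record_hdf5(tmp_path / "r.h5")
        assert back.start_offset_s == 42.0
        assert back.channels[0].name == "a"
        assert np.array_equal(back.channels[0].samples, rec.channels[0].samples)

    def test_scored_region_tsv(self, tmp_path):
        (tmp_path / "r.tsv").write_text("12.5\t3600.0\n")
        region = read_scored_region(tmp_path / "r.tsv")
        assert (region.onset_s, region.offset_s) == (12.5, 3600.0)
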