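"""Record I/O, resampling, windowing and label expansion."""

import numpy as np
import pytest

from shemon import signal_io as sio
from shemon.synth import EcgSynthConfig, synth_ecg


class TestReadWrite:
    def test_csv_identity_read(self, tmp_path):
        rec = sio.EcgRecord(np.sin(np.arange(2500) / 40.0), fs=250)
        sio.write_record(rec, tmp_path / "r.csv")
        back = sio.read_record(tmp_path / "r.csv")
        assert len(back.samples) == 2500
        assert back.fs == 250
        np.testing.assert_array_equal(back.samples, rec.samples)

    def test_csv_roundtrip_with_labels(self, tmp_path):
        rec = synth_ecg(EcgSynthConfig(duration_s=10, seed=3,
                                       ectopic=[("V", 12.0)]))
        sio.write_record(rec, tmp_path / "r.csv")
        back = sio.read_record(tmp_path / "r.csv")
        np.testing.assert_array_equal(back.samples, rec.samples)
        assert back.beat_labels == rec.beat_labels

    def test_wfdb_roundtrip_preserves_fs_and_annotations(self, tmp_path):
        rec = synth_ecg(EcgSynthConfig(duration_s=10, seed=3, fs=1000.0,
                                       ectopic=[("V", 12.0), ("S", 6.0)]))
        sio.write_wfdb(rec, tmp_path, "rec1", gain=2000)
        back = sio.read_record(tmp_path / "rec1.hea")
        assert back.fs == 1000.0  # native rate preserved, no silent resampling
        assert back.beat_labels == rec.beat_labels
        assert np.abs(back.samples - rec.samples).max() < 1e-3  # ADC rounding

    def test_wfdb_format_212(self, tmp_path):
        adc = np.round(1000 * np.sin(np.arange(1000) / 7.0)).astype(np.int32)
        buf = bytearray()
        for i in range(0, len(adc), 2):
            s0, s1 = int(adc[i]) & 0xFFF, int(adc[i + 1]) & 0xFFF
            buf += bytes([s0 & 0xFF,
                          ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4),
                          s1 & 0xFF])
        (tmp_path / "x.dat").write_bytes(bytes(buf))
        (tmp_path / "x.hea").write_text(
            "x 1 250 1000\nx.dat 212 200(0)/mV 12 0 0 0 0 V2\n")
        rec = sio.read_record(tmp_path / "x.hea")
        assert rec.lead == "V2"
        np.testing.assert_allclose(rec.samples, adc / 200.0)

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            sio.read_record(tmp_path / "missing.hea", format="wfdb")


class TestResample:
    def test_1000_to_250_length(self):
        rec = sio.EcgRecord(np.random.default_rng(0).normal(size=8000), fs=1000)
        out = sio.resample(rec, 250)
        assert abs(len(out.samples) - 2000) <= 1
        assert out.fs == 250

    def test_identity_when_target_equals_fs(self, clean_ecg_60s):
        out = sio.resample(clean_ecg_60s, clean_ecg_60s.fs)
        np.testing.assert_array_equal(out.samples, clean_ecg_60s.samples)
        assert out.beat_labels == clean_ecg_60s.beat_labels

    def test_257_to_250_preserves_sine(self):
        t = np.arange(0, 10, 1 / 257.0)
        rec = sio.EcgRecord(np.sin(2 * np.pi * 5 * t), fs=257)
        out = sio.resample(rec, 250)
        spec = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(len(out.samples), 1 / 250.0)
        assert abs(freqs[spec.argmax()] - 5.0) / 5.0 < 0.01
        assert abs(2 * spec.max() / len(out.samples) - 1.0) < 0.01

    def test_down_up_roundtrip_keeps_frequency(self):
        t = np.arange(0, 4, 1e-3)
        rec = sio.EcgRecord(np.sin(2 * np.pi * 17 * t), fs=1000)
        back = sio.resample(sio.resample(rec, 250), 1000)
        spec = np.abs(np.fft.rfft(back.samples))
        freqs = np.fft.rfftfreq(len(back.samples), 1e-3)
        assert abs(freqs[spec.argmax()] - 17.0) / 17.0 < 1e-3

    def test_beat_indices_rescaled(self):
        rec = sio.EcgRecord(np.zeros(8000), fs=1000,
                            beat_labels=[(1000, "N"), (5000, "V")])
        out = sio.resample(rec, 250)
        assert out.beat_labels == [(250, "N"), (1250, "V")]

    def test_empty_record_rejected(self):
        # an all-empty trace cannot be constructed resample-ready
        rec = sio.EcgRecord(np.zeros(10), fs=250)
        rec.samples = np.zeros(0)
        with pytest.raises(ValueError):
            sio.resample(rec, 100)


class TestWindows:
    def test_60s_gives_7_windows(self, clean_ecg_60s):
        ws = sio.make_windows(clean_ecg_60s)
        assert len(ws) == 7
        assert all(len(w.x) == 2000 and len(w.y) == 2000 for w in ws)

    def test_exactly_one_window(self):
        rec = sio.EcgRecord(np.zeros(2000), fs=250)
        assert len(sio.make_windows(rec)) == 1

    def test_short_record_empty(self):
        rec = sio.EcgRecord(np.zeros(int(7.9 * 250)), fs=250)
        with pytest.warns(UserWarning):
            assert sio.make_windows(rec) == []

    def test_windowing_is_lossless_on_covered_prefix(self):
        rec = synth_ecg(EcgSynthConfig(duration_s=20, seed=5,
                                       ectopic=[("V", 20.0)]))
        full = sio.expand_labels(rec)
        ws = sio.make_windows(rec)
        recon = np.concatenate([w.y for w in ws])
        np.testing.assert_array_equal(recon, full[:len(recon)])


class TestExpandLabels:
    def test_no_annotations_all_background(self):
        rec = sio.EcgRecord(np.zeros(1000), fs=250)
        assert (sio.expand_labels(rec) == 0).all()

    def test_veb_neighborhood_count(self):
        rec = sio.EcgRecord(np.zeros(2500), fs=250, beat_labels=[(1000, "V")])
        y = sio.expand_labels(rec)
        assert (y == sio.DEFAULT_CLASS_SCHEME["V"]).sum() == 151

    def test_beat_class_wins_over_rhythm(self):
        rec = sio.EcgRecord(np.zeros(2500), fs=250, beat_labels=[(1000, "F")],
                            rhythm_label="MI")
        y = sio.expand_labels(rec)
        # brute-force paint: rhythm everywhere, beat overrides its window
        expect = np.full(2500, sio.DEFAULT_CLASS_SCHEME["MI"])
        expect[925:1076] = sio.DEFAULT_CLASS_SCHEME["F"]
        np.testing.assert_array_equal(y, expect)

    def test_deterministic(self):
        rec = synth_ecg(EcgSynthConfig(duration_s=10, seed=9,
                                       ectopic=[("S", 30.0)]))
        np.testing.assert_array_equal(sio.expand_labels(rec),
                                      sio.expand_labels(rec))

    def test_unmapped_symbol_raises_naming_it(self):
        rec = sio.EcgRecord(np.zeros(1000), fs=250, beat_labels=[(500, "Z!")])
        with pytest.raises(KeyError, match="Z!"):
            sio.expand_labels(rec)


def test_hdf5_dataset_roundtrip(tmp_path):
    X = np.random.default_rng(0).normal(size=(4, 2000)).astype(np.float32)
    Y = np.random.default_rng(1).integers(0, 9, size=(4, 2000))
    sio.save_dataset(tmp_path / "d.h5", X, Y)
    X2, Y2, fs, names = sio.load_dataset(tmp_path / "d.h5")
    np.testing.assert_allclose(X2, X)
    np.testing.assert_array_equal(Y2, Y)
    assert fs == 250.0 and list(names) == list(sio.CLASS_NAMES)


def test_record_invariants_enforced():
    with pytest.raises(ValueError):
        sio.EcgRecord(np.zeros(10), fs=0)
    with pytest.raises(ValueError):
        sio.EcgRecord(np.array([1.0, np.nan]), fs=250)
    with pytest.raises(ValueError):
        sio.EcgRecord(np.zeros(10), fs=250, beat_labels=[(5, "N"), (5, "V")])
    with pytest.raises(ValueError):
        sio.EcgRecord(np.zeros(10), fs=250, beat_labels=[(20, "N")])
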