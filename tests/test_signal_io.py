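"""Recording I/O, event tables and epoch extraction."""

import logging

import numpy as np
import pytest

import neuroload as nl
from neuroload.errors import (
    EmptyInputError,
    PreconditionError,
    SamplingError,
)
from neuroload.signal_io import Event, EventTable


def make_recording(n_ch=2, n_samp=100, fs=128.0, seed=0):
    rng = np.random.default_rng(seed)
    return nl.Recording(fs, [f"C{i}" for i in range(n_ch)],
                        rng.standard_normal((n_ch, n_samp)) * 10)


class TestRecording:
    def test_shape_and_label_mismatch_rejected(self):
        with pytest.raises(PreconditionError):
            nl.Recording(128.0, ["A"], np.zeros((2, 10)))

    def test_nonfinite_rejected(self):
        data = np.zeros((1, 5))
        data[0, 2] = np.nan
        with pytest.raises(PreconditionError):
            nl.Recording(128.0, ["A"], data)

    def test_canonical_labels_accepted_in_order(self):
        rec = nl.Recording(128.0, list(nl.CANONICAL_CHANNELS),
                           np.zeros((14, 8)))
        assert rec.channels == list(nl.CANONICAL_CHANNELS)


class TestCsvRoundTrip:
    def test_small_csv_construction(self, tmp_path):
        # 3 samples, 2 channels at dt = 1/128 s
        p = tmp_path / "r.csv"
        p.write_text(
            "time,A,B\n0.0,1.0,4.0\n0.0078125,2.0,5.0\n0.015625,3.0,6.0\n"
        )
        rec = nl.read_recording(p)
        assert rec.fs == pytest.approx(128.0)
        assert rec.data.shape == (2, 3)
        assert rec.channels == ["A", "B"]
        np.testing.assert_allclose(rec.data[0], [1, 2, 3])

    def test_round_trip_lossless(self, tmp_path):
        rec = make_recording()
        nl.write_recording(rec, tmp_path / "r.csv")
        back = nl.read_recording(tmp_path / "r.csv")
        assert back.fs == pytest.approx(rec.fs)
        np.testing.assert_allclose(back.data, rec.data, atol=1e-9)

    def test_jittered_time_column_rejected(self, tmp_path):
        rng = np.random.default_rng(3)
        t = np.arange(50) / 128.0
        t += rng.uniform(-0.02, 0.02, size=t.size) / 128.0 * 4  # ~3% jitter
        t = np.sort(t)
        lines = ["time,A"] + [f"{ti},{i}" for i, ti in enumerate(t)]
        p = tmp_path / "j.csv"
        p.write_text("\n".join(lines))
        with pytest.raises(SamplingError):
            nl.read_recording(p)


class TestEdfRoundTrip:
    def test_round_trip_within_quantization(self, tmp_path):
        rec = make_recording(n_ch=3, n_samp=500)
        nl.write_recording(rec, tmp_path / "r.edf")
        back = nl.read_recording(tmp_path / "r.edf")
        assert back.fs == pytest.approx(rec.fs)
        assert back.channels == rec.channels
        # 16-bit quantization over the per-channel amplitude span
        span = np.ptp(rec.data, axis=1).max()
        assert np.abs(back.data - rec.data).max() < span / 2**15

    def test_synthetic_recording_round_trip(self, tmp_path):
        rec, _ = nl.generate(seed=1, schedule=(("cruise", 30.0),))
        nl.write_recording(rec, tmp_path / "s.edf")
        back = nl.read_recording(tmp_path / "s.edf")
        span = np.ptp(rec.data, axis=1).max()
        assert np.abs(back.data - rec.data).max() < span / 2**15

    def test_mne_reads_our_edf(self, tmp_path):
        """Independent reader oracle: mne parses the files we write."""
        mne = pytest.importorskip("mne")
        rec = make_recording(n_ch=2, n_samp=256)
        nl.write_recording(rec, tmp_path / "r.edf")
        raw = mne.io.read_raw_edf(tmp_path / "r.edf", verbose="error")
        assert raw.info["sfreq"] == pytest.approx(rec.fs)
        np.testing.assert_allclose(
            raw.get_data() * 1e6, rec.data, atol=np.ptp(rec.data) / 2**14
        )

    def test_zero_length_refused(self, tmp_path):
        rec = nl.Recording(128.0, ["A"], np.empty((1, 0)))
        with pytest.raises(EmptyInputError):
            nl.write_recording(rec, tmp_path / "z.edf")


class TestEventTable:
    def test_overlap_rejected(self):
        with pytest.raises(PreconditionError):
            EventTable([Event(0, 10, "cruise"), Event(5, 10, "turn_left")])

    def test_tsv_round_trip(self, tmp_path):
        table = EventTable([Event(0, 10, "cruise"), Event(10, 5, "turn_left")])
        table.to_tsv(tmp_path / "e.tsv")
        back = EventTable.from_tsv(tmp_path / "e.tsv")
        assert back.phases == ["cruise", "turn_left"]
        assert back.events[1].duration_s == pytest.approx(5)


class TestExtractEpochs:
    @pytest.mark.parametrize(
        "duration,window,overlap,expected",
        [
            (10.0, 2.0, 0.0, 5),    # integer division
            (10.0, 2.0, 0.5, 9),    # (10-2)/1 + 1
            (1.0, 2.0, 0.0, 0),     # event shorter than window
        ],
    )
    def test_epoch_count_formula(self, duration, window, overlap, expected, caplog):
        fs = 128.0
        n = int(duration * fs) + 10
        rec = nl.Recording(fs, ["A"], np.zeros((1, n)))
        events = EventTable([Event(0.0, duration, "cruise")])
        with caplog.at_level(logging.WARNING):
            eps = nl.extract_epochs(rec, events, window, overlap)
        assert eps.n_epochs == expected
        if expected == 0:
            assert "skipped" in caplog.text

    def test_epochs_stay_inside_events_and_inherit_labels(self):
        fs = 64.0
        rec = make_recording(n_ch=1, n_samp=int(fs * 40), fs=fs)
        events = EventTable(
            [Event(0, 10, "cruise"), Event(12, 8, "turn_left"), Event(25, 10, "turn_right")]
        )
        eps = nl.extract_epochs(rec, events, window_s=2.0, overlap_frac=0.5)
        win = int(2.0 * fs)
        hop = win // 2
        # reconstruct each epoch's position and check containment
        starts = []
        for ev in events:
            s0 = int(round(ev.onset_s * fs))
            dur = int(round(ev.duration_s * fs))
            k = (dur - win) // hop + 1
            starts += [(s0 + i * hop, ev.phase) for i in range(k)]
        assert eps.n_epochs == len(starts)
        for i, (s0, phase) in enumerate(starts):
            np.testing.assert_array_equal(eps.epochs[i, 0], rec.data[0, s0:s0 + win])
            assert eps.labels[i] == phase

    def test_event_outside_recording_rejected(self):
        rec = make_recording(n_samp=100)
        events = EventTable([Event(0, 100.0, "cruise")])
        with pytest.raises(PreconditionError):
            nl.extract_epochs(rec, events, 2.0, 0.0)
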