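"""EDF round trip, preprocessing, epoch extraction and rest balancing."""

import numpy as np
import pytest

from miaug import EpochSet, SyntheticSpec, generate_dataset
from miaug.dataio import (
    PHYSIONET_CODE_MAP,
    RawRecording,
    balance_rest,
    exclude_channels,
    extract_epochs,
    notch_filter,
    read_edf,
    write_edf,
)

FS = 160


@pytest.fixture()
def recording(rng):
    signal = rng.normal(0.0, 20.0, size=(6, FS * 20))
    ann = [(160, 640, "T1"), (1120, 640, "T2"), (2080, 640, "T0"), (2880, 640, "BAD")]
    names = ["C3", "C4", "CZ", "PZ", "O1", "O2"]
    return RawRecording(signal=signal, fs=FS, channel_names=names, annotations=ann)


class TestEDFRoundTrip:
    def test_signal_survives_within_quantization(self, recording, tmp_path):
        path = write_edf(tmp_path / "rec.edf", recording)
        back = read_edf(path)
        # worst-case error is one 16-bit step over each channel's physical range
        step = (recording.signal.max(axis=1) - recording.signal.min(axis=1)) / (2**16 - 1)
        err = np.abs(back.signal - recording.signal).max(axis=1)
        assert np.all(err <= step)
        assert back.fs == FS
        assert back.channel_names == recording.channel_names
        assert len(back.channel_names) == 6

    def test_annotation_codes_preserved_verbatim(self, recording, tmp_path):
        back = read_edf(write_edf(tmp_path / "rec.edf", recording))
        codes = [c for _, _, c in back.annotations]
        assert codes == ["T1", "T2", "T0", "BAD"]
        onsets = [o for o, _, _ in back.annotations]
        assert onsets == [160, 1120, 2080, 2880]

    def test_nonexistent_path(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_edf(tmp_path / "missing.edf")

    def test_garbled_file(self, tmp_path):
        bad = tmp_path / "junk.edf"
        bad.write_bytes(b"this is not an EDF file at all" * 10)
        with pytest.raises(ValueError):
            read_edf(bad)


class TestExcludeChannels:
    def test_empty_list_is_identity(self, recording):
        out = exclude_channels(recording, [])
        assert out.channel_names == recording.channel_names
        assert np.array_equal(out.signal, recording.signal)

    def test_present_names_removed_order_preserved(self, recording):
        out = exclude_channels(recording, ["C4", "O1"])
        assert out.channel_names == ["C3", "CZ", "PZ", "O2"]
        assert np.array_equal(out.signal[0], recording.signal[0])
        assert np.array_equal(out.signal[1], recording.signal[2])

    def test_absent_name_ignored(self, recording, caplog):
        out = exclude_channels(recording, ["A1"])
        assert out.channel_names == recording.channel_names


class TestNotchFilter:
    t = np.arange(FS * 4) / FS

    def test_mains_attenuation_fft_oracle(self):
        sine = np.sin(2 * np.pi * 60.0 * self.t)[None, :]
        out = notch_filter(sine, 60.0, FS)
        k = int(round(60.0 * sine.shape[-1] / FS))
        amp = np.abs(np.fft.rfft(out[0]))
        assert amp[k] < 0.05 * np.abs(np.fft.rfft(sine[0]))[k]

    def test_passband_preservation(self):
        sine = np.sin(2 * np.pi * 10.0 * self.t)[None, :]
        out = notch_filter(sine, 60.0, FS)
        assert np.sqrt(np.mean(out**2)) == pytest.approx(np.sqrt(np.mean(sine**2)), rel=0.02)

    def test_zero_in_zero_out(self):
        assert not notch_filter(np.zeros((3, 640)), 60.0, FS).any()

    def test_rejects_frequency_at_or_above_nyquist(self):
        with pytest.raises(ValueError):
            notch_filter(np.zeros((1, 640)), 80.0, FS)

    def test_second_application_changes_little(self):
        # A maximally flat band-stop still attenuates band-edge energy a
        # second time, so idempotence holds only approximately: the bound
        # reflects the filter's real passband behaviour on broadband EEG.
        ds = generate_dataset(SyntheticSpec(n_subjects=1, epochs_per_class_per_subject=5,
                                            n_channels=8, n_samples=640, seed=0))
        once = notch_filter(ds.data, 60.0, FS)
        twice = notch_filter(once, 60.0, FS)
        rel = np.sqrt(np.mean((twice - once) ** 2) / np.mean(once**2))
        assert rel < 0.05

    def test_shape_preserved_for_epoch_stacks(self):
        x = np.random.default_rng(0).normal(size=(4, 3, 320))
        assert notch_filter(x, 60.0, FS).shape == x.shape


class TestExtractEpochs:
    def test_one_epoch_per_mapped_cue(self, recording):
        es = extract_epochs(recording, PHYSIONET_CODE_MAP, 640, subject_id="S001")
        assert es.n_epochs == 3  # "BAD" is unmapped
        assert es.data.shape == (3, 6, 640)
        assert list(es.labels) == ["LEFT", "RIGHT", "REST"]
        assert set(es.subjects) == {"S001"}

    def test_epoch_equals_raw_slice_exactly(self, recording):
        es = extract_epochs(recording, PHYSIONET_CODE_MAP, 640)
        assert np.array_equal(es.data[0], recording.signal[:, 160 : 160 + 640])

    def test_window_past_end_is_dropped(self, rng):
        rec = RawRecording(rng.normal(size=(2, 1000)), FS, ["C3", "C4"],
                          [(100, 640, "T1"), (500, 640, "T2")])
        es = extract_epochs(rec, PHYSIONET_CODE_MAP, 640)
        assert es.n_epochs == 1
        assert list(es.labels) == ["LEFT"]

    def test_empty_map_gives_empty_set(self, recording):
        assert extract_epochs(recording, {}, 640).n_epochs == 0


class TestBalanceRest:
    def _epochs(self, n_rest=15, n_left=8, n_right=8, subject="S001"):
        n = n_rest + n_left + n_right
        labels = ["REST"] * n_rest + ["LEFT"] * n_left + ["RIGHT"] * n_right
        return EpochSet(
            data=np.arange(n * 2 * 4, dtype=float).reshape(n, 2, 4),
            labels=np.array(labels, dtype=object),
            subjects=np.array([subject] * n, dtype=object),
            fs=FS,
            channel_names=["C3", "C4"],
        )

    def test_rest_reduced_to_min_hand_count(self):
        out = balance_rest(self._epochs(15, 8, 8), seed=0)
        assert out.class_counts() == {"LEFT": 8, "RIGHT": 8, "REST": 8}

    def test_already_balanced_untouched(self):
        es = self._epochs(8, 8, 8)
        out = balance_rest(es, seed=0)
        assert np.array_equal(np.sort(out.data, axis=0), np.sort(es.data, axis=0))

    def test_same_seed_identical_selection(self):
        a = balance_rest(self._epochs(), seed=3)
        b = balance_rest(self._epochs(), seed=3)
        assert np.array_equal(a.data, b.data)

    def test_subject_without_rest_kept(self):
        es = self._epochs(0, 4, 4)
        out = balance_rest(es, seed=0)
        assert out.n_epochs == 8


def test_epochset_persistence_round_trip(tmp_path, small_dataset):
    path = small_dataset.save(tmp_path / "epochs")
    back = EpochSet.load(path)
    assert np.array_equal(back.data, small_dataset.data)
    assert np.array_equal(back.labels, small_dataset.labels)
    assert np.array_equal(back.subjects, small_dataset.subjects)
    assert back.fs == small_dataset.fs
    assert back.channel_names == small_dataset.channel_names
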