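"""Reading EDF+ recordings, epoch extraction and minimal preprocessing.

Preprocessing is intentionally minimal: optional channel exclusion, an
optional zero-phase 60 Hz notch, fixed-length epoching at cue onsets, and
per-subject rest-class balancing.  No re-referencing and no artifact
rejection — the classifier is meant to see near-raw data.

EDF+ files are read through :mod:`mne`.  A small EDF+C writer is included
(16-bit samples, standard physical/digital scaling, one TAL annotation
channel) so synthetic recordings can be exported and round-tripped in tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import CLASSES, EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording",
    "PreprocessConfig",
    "EXCLUDED_CHANNELS",
    "PHYSIONET_CODE_MAP",
    "read_edf",
    "write_edf",
    "exclude_channels",
    "notch_filter",
    "extract_epochs",
    "balance_rest",
]

#: Electrode names excluded from analysis (applied permissively: names not
#: present in a recording are simply ignored with a log entry).
EXCLUDED_CHANNELS: list[str] = ["NZ", "F9", "F10", "FT9", "FT10", "A1", "A2", "TP9", "TP10", "P9", "P10"]

#: Annotation-code mapping for the PhysioNet motor-imagery runs
#: (T0 = rest, T1 = left-hand imagery, T2 = right-hand imagery).
PHYSIONET_CODE_MAP: dict[str, str] = {"T0": "REST", "T1": "LEFT", "T2": "RIGHT"}


@dataclass
class RawRecording:
    """A continuous multichannel recording with event annotations.

    ``annotations`` is a list of ``(onset_sample, duration_samples, code)``
    tuples, onsets in 0-based sample coordinates.
    """

    signal: np.ndarray  # (n_channels, n_samples), µV
    fs: float
    channel_names: list[str]
    annotations: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channel, sample)")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must equal channel count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for onset, _dur, _code in self.annotations:
            if not 0 <= onset < self.signal.shape[1]:
                raise ValueError(f"annotation onset {onset} outside the recording")


@dataclass
class PreprocessConfig:
    excluded_channels: list[str] = field(default_factory=lambda: list(EXCLUDED_CHANNELS))
    notch_enabled: bool = True
    notch_freq: float = 60.0
    epoch_samples: int = 640
    balance_rest: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_samples < 1:
            raise ValueError("epoch_samples must be >= 1")


# ---------------------------------------------------------------------------
# EDF reading / writing


def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF/EDF+ file into a :class:`RawRecording` (µV).

    Annotation codes are preserved verbatim (PhysioNet uses T0/T1/T2).
    A file without annotations yields an empty list and a logged warning.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # garbled/unparseable file
        raise ValueError(f"could not parse {path} as EDF/EDF+: {exc}") from exc
    fs = float(raw.info["sfreq"])
    signal = raw.get_data(units="uV")
    annotations = [
        (int(round(onset * fs)), int(round(dur * fs)), str(desc))
        for onset, dur, desc in zip(raw.annotations.onset, raw.annotations.duration,
                                    raw.annotations.description)
    ]
    if not annotations:
        logger.warning("no annotations found in %s", path)
    return RawRecording(signal=signal, fs=fs, channel_names=list(raw.ch_names), annotations=annotations)


def _pad16(s: str, width: int) -> bytes:
    b = s.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, rec: RawRecording) -> Path:
    """Write a :class:`RawRecording` as a 16-bit EDF+C file.

    One-second data records; the signal length must be a whole number of
    records.  Quantization: each channel is scaled to the int16 range from
    its own physical min/max, so the worst-case round-trip error is half of
    one quantization step, ``(phys_max - phys_min) / 2**16 / 2``.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.signal.shape
    if n_samp % fs:
        raise ValueError("signal length must be a whole number of 1 s records")
    n_rec = n_samp // fs
    ann_len = 60  # int16 samples reserved for the TAL channel per record

    pmins = rec.signal.min(axis=1)
    pmaxs = rec.signal.max(axis=1)
    flat = pmaxs - pmins <= 0
    pmins[flat] -= 1.0
    pmaxs[flat] += 1.0
    dmin, dmax = -32768, 32767

    ns = n_ch + 1
    header = b"".join([
        _pad16("0", 8),
        _pad16("X X X X", 80),
        _pad16("Startdate X X X X", 80),
        _pad16("01.01.00", 8),
        _pad16("00.00.00", 8),
        _pad16(str(256 * (ns + 1)), 8),
        _pad16("EDF+C", 44),
        _pad16(str(n_rec), 8),
        _pad16("1", 8),
        _pad16(str(ns), 4),
    ])
    labels = [_pad16(name, 16) for name in rec.channel_names] + [_pad16("EDF Annotations", 16)]
    transducers = [_pad16("", 80)] * ns
    dims = [_pad16("uV", 8)] * n_ch + [_pad16("", 8)]
    phys_min = [_pad16(f"{v:.8g}"[:8], 8) for v in pmins] + [_pad16("-1", 8)]
    phys_max = [_pad16(f"{v:.8g}"[:8], 8) for v in pmaxs] + [_pad16("1", 8)]
    dig_min = [_pad16(str(dmin), 8)] * ns
    dig_max = [_pad16(str(dmax), 8)] * ns
    prefilter = [_pad16("", 80)] * ns
    spr = [_pad16(str(fs), 8)] * n_ch + [_pad16(str(ann_len), 8)]
    reserved = [_pad16("", 32)] * ns
    header += b"".join(b"".join(x) for x in
                       (labels, transducers, dims, phys_min, phys_max, dig_min, dig_max,
                        prefilter, spr, reserved))

    scale = (pmaxs - pmins) / (dmax - dmin)
    digital = np.round((rec.signal - pmins[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    by_record: dict[int, list[tuple[int, int, str]]] = {}
    for onset, dur, code in rec.annotations:
        by_record.setdefault(onset // fs, []).append((onset, dur, code))

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            f.write(digital[:, r * fs : (r + 1) * fs].tobytes())
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            for onset, dur, code in by_record.get(r, []):
                tal += f"+{onset / fs:g}\x15{dur / fs:g}\x14{code}\x14\x00".encode("ascii")
            if len(tal) > 2 * ann_len:
                raise ValueError("too many annotations in one record for the TAL channel")
            f.write(tal + b"\x00" * (2 * ann_len - len(tal)))
    return path


# ---------------------------------------------------------------------------
# preprocessing


def exclude_channels(rec: RawRecording, names: list[str]) -> RawRecording:
    """Drop the named channels; order of the remainder is preserved.

    Names absent from the recording are ignored (logged), so a standard
    exclusion list can be applied to any montage permissively.
    """
    wanted = {n.upper() for n in names}
    present = {n.upper() for n in rec.channel_names}
    missing = wanted - present
    if missing:
        logger.warning("exclusion names not present in recording: %s", sorted(missing))
    keep = [i for i, n in enumerate(rec.channel_names) if n.upper() not in wanted]
    return RawRecording(
        signal=rec.signal[keep].copy(),
        fs=rec.fs,
        channel_names=[rec.channel_names[i] for i in keep],
        annotations=list(rec.annotations),
    )


def notch_filter(x: np.ndarray, f0: float = 60.0, fs: float = 160.0,
                 bandwidth: float = 4.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-stop around ``f0`` (default 58–62 Hz).

    Works on any array whose last axis is time (a raw recording, one epoch,
    or a stack of epochs); the output has the same shape.
    """
    if not 0.0 < f0 < fs / 2.0:
        raise ValueError(f"notch frequency {f0} must lie in (0, fs/2)")
    lo, hi = f0 - bandwidth / 2.0, f0 + bandwidth / 2.0
    sos = butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def extract_epochs(rec: RawRecording, code_to_label: dict[str, str],
                   epoch_samples: int = 640, subject_id: str = "S000") -> EpochSet:
    """One epoch per mapped annotation: window ``[onset, onset + epoch_samples)``.

    Windows are 0-based and half-open, aligned at the cue onset with no
    pre-cue baseline.  Unmapped codes are skipped; a trial whose window runs
    past the end of the recording is dropped with a log entry.
    """
    bad = set(code_to_label.values()) - set(CLASSES)
    if bad:
        raise ValueError(f"code map targets unknown labels {sorted(bad)}")
    data, labels = [], []
    n = rec.signal.shape[1]
    for onset, _dur, code in rec.annotations:
        if code not in code_to_label:
            continue
        if onset + epoch_samples > n:
            logger.warning("dropping trial at sample %d: window exceeds recording", onset)
            continue
        data.append(rec.signal[:, onset : onset + epoch_samples].copy())
        labels.append(code_to_label[code])
    if not data:
        data_arr = np.empty((0, rec.signal.shape[0], epoch_samples))
    else:
        data_arr = np.stack(data)
    return EpochSet(
        data=data_arr,
        labels=np.array(labels, dtype=object),
        subjects=np.array([subject_id] * len(labels), dtype=object),
        fs=rec.fs,
        channel_names=list(rec.channel_names),
    )


def balance_rest(epochs: EpochSet, seed: int = 0) -> EpochSet:
    """Balance the rest class per subject down to min(LEFT, RIGHT) count.

    Rest epochs are subsampled without replacement (seeded); left/right
    epochs are untouched.  A subject with no rest epochs is kept as-is with
    a warning.
    """
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for subject in dict.fromkeys(epochs.subjects):  # preserves first-seen order
        sub_idx = np.flatnonzero(epochs.subjects == subject)
        sub_labels = epochs.labels[sub_idx]
        rest = sub_idx[sub_labels == "REST"]
        n_left = int(np.sum(sub_labels == "LEFT"))
        n_right = int(np.sum(sub_labels == "RIGHT"))
        target = min(n_left, n_right)
        if rest.size == 0:
            logger.warning("subject %s has no REST epochs; left unbalanced", subject)
            keep.extend(sub_idx.tolist())
            continue
        chosen = rest if rest.size <= target else np.sort(rng.choice(rest, size=target, replace=False))
        keep.extend(i for i in sub_idx if epochs.labels[i] != "REST")
        keep.extend(chosen.tolist())
    return epochs.select(sorted(keep))
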