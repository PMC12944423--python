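"""Core data containers shared by every stage of the pipeline.

The central object is :class:`EpochSet`: a stack of fixed-length multichannel
EEG epochs (``µV``) with per-epoch class label and subject identifier.  Epochs
are the unit of classification throughout — splitting, augmentation, model
training and evaluation all consume and produce ``EpochSet`` instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Canonical class order used everywhere (label strings and score columns).
CLASSES: tuple[str, ...] = ("LEFT", "RIGHT", "REST")

#: Subject sentinel attached to epochs produced by a generative model.
SYNTHETIC_SUBJECT = "synthetic"


def class_index(label: str) -> int:
    """Map a class label to its canonical integer index."""
    try:
        return CLASSES.index(label)
    except ValueError:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}") from None


@dataclass
class EpochSet:
    """Labeled multichannel EEG epochs.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Signal amplitudes in microvolts.
    labels : ndarray of str, shape (n_epochs,)
        Class label per epoch, drawn from :data:`CLASSES`.
    subjects : ndarray of str, shape (n_epochs,)
        Subject identifier per epoch.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Ordered channel names, one per channel row.
    """

    data: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (epoch, channel, sample), got shape {self.data.shape}")
        n = self.data.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal the number of epochs")
        if self.subjects.shape != (n,):
            raise ValueError("subjects length must equal the number of epochs")
        if self.channel_names and len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal the number of channels")
        if not self.channel_names:
            self.channel_names = [f"CH{i:02d}" for i in range(self.data.shape[1])]
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if n and not np.isfinite(self.data).all():
            raise ValueError("epoch data contains NaN or Inf")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown labels {sorted(map(str, bad))}; expected subset of {CLASSES}")

    # ------------------------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASSES}

    def label_indices(self) -> np.ndarray:
        """Integer labels in canonical :data:`CLASSES` order."""
        return np.array([class_index(l) for l in self.labels], dtype=int)

    def select(self, idx: Sequence[int] | np.ndarray) -> "EpochSet":
        """Return a new EpochSet holding the epochs at ``idx`` (copy)."""
        idx = np.asarray(idx, dtype=int)
        return EpochSet(
            data=self.data[idx].copy(),
            labels=self.labels[idx].copy(),
            subjects=self.subjects[idx].copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
        )

    @staticmethod
    def concatenate(parts: Iterable["EpochSet"]) -> "EpochSet":
        parts = list(parts)
        if not parts:
            raise ValueError("cannot concatenate an empty list of EpochSets")
        ref = parts[0]
        for p in parts[1:]:
            if p.fs != ref.fs or p.channel_names != ref.channel_names:
                raise ValueError("EpochSets differ in fs or channel layout")
            if p.data.shape[1:] != ref.data.shape[1:]:
                raise ValueError("EpochSets differ in epoch shape")
        return EpochSet(
            data=np.concatenate([p.data for p in parts], axis=0),
            labels=np.concatenate([p.labels for p in parts]),
            subjects=np.concatenate([p.subjects for p in parts]),
            fs=ref.fs,
            channel_names=list(ref.channel_names),
        )

    # ------------------------------------------------------------------
    # Persistence: one compressed array file + JSON sidecar, bit-exact.
    def save(self, path: str | Path) -> Path:
        """Persist to ``<path>.npz`` plus a ``<path>.json`` sidecar.

        The round trip is bit-exact: arrays are stored as float64 and
        metadata (labels, subjects, channel names, fs) in the sidecar.
        """
        path = Path(path)
        base = path.with_suffix("") if path.suffix == ".npz" else path
        np.savez_compressed(base.with_suffix(".npz"), data=self.data)
        meta = {
            "labels": [str(l) for l in self.labels],
            "subjects": [str(s) for s in self.subjects],
            "fs": float(self.fs),
            "channel_names": self.channel_names,
        }
        base.with_suffix(".json").write_text(json.dumps(meta))
        return base.with_suffix(".npz")

    @staticmethod
    def load(path: str | Path) -> "EpochSet":
        base = Path(path)
        base = base.with_suffix("") if base.suffix in {".npz", ".json"} else base
        with np.load(base.with_suffix(".npz")) as npz:
            data = npz["data"]
        meta = json.loads(base.with_suffix(".json").read_text())
        return EpochSet(
            data=data,
            labels=np.array(meta["labels"], dtype=object),
            subjects=np.array(meta["subjects"], dtype=object),
            fs=meta["fs"],
            channel_names=meta["channel_names"],
        )


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (0.5 -> 1)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0
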