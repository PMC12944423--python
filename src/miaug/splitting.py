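"""Leakage-controlled train/test partitioning strategies.

Three strategies, all 80:20 by default:

* **Pooled Random Split** — every epoch is treated as an independent sample
  and assigned uniformly at random.
* **Patient Leave-P-Out** — whole subjects are assigned to one side, so the
  test set measures cross-subject generalization.
* **Intra-Patient Then Pool** — each subject's epochs are split 80:20
  (class-stratified) and the per-subject sides are pooled.

Augmentation is applied strictly after splitting and only to the training
partition (the cascade layer's API accepts only the train side); this module
additionally provides an explicit no-leakage verifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import CLASSES, EpochSet, round_half_away

__all__ = [
    "SplitResult",
    "LeakageReport",
    "pooled_random_split",
    "patient_leave_p_out",
    "intra_patient_then_pool",
    "split",
    "verify_no_leakage",
    "STRATEGIES",
]

POOLED_RANDOM = "POOLED_RANDOM"
PATIENT_LEAVE_P_OUT = "PATIENT_LEAVE_P_OUT"
INTRA_PATIENT_THEN_POOL = "INTRA_PATIENT_THEN_POOL"
STRATEGIES = (POOLED_RANDOM, PATIENT_LEAVE_P_OUT, INTRA_PATIENT_THEN_POOL)


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    strategy: str
    seed: int

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(sorted(self.train_idx), dtype=int)
        self.test_idx = np.asarray(sorted(self.test_idx), dtype=int)
        if self.train_idx.size == 0 or self.test_idx.size == 0:
            raise ValueError("both partitions must be nonempty")
        # disjointness is *verified*, not enforced, so that verify_no_leakage
        # can report a corrupted split instead of never seeing one

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "strategy": self.strategy,
            "seed": self.seed,
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
        })
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @staticmethod
    def from_json(source: str | Path) -> "SplitResult":
        text = Path(source).read_text() if isinstance(source, Path) else source
        d = json.loads(text)
        return SplitResult(np.array(d["train_idx"]), np.array(d["test_idx"]), d["strategy"], d["seed"])


def pooled_random_split(epochs: EpochSet, train_frac: float = 0.8, seed: int = 0) -> SplitResult:
    """Uniform random 80:20 assignment of pooled epochs."""
    n = epochs.n_epochs
    if n < 2:
        raise ValueError("need at least 2 epochs to split")
    n_train = round_half_away(train_frac * n)
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitResult(perm[:n_train], perm[n_train:], POOLED_RANDOM, seed)


def patient_leave_p_out(epochs: EpochSet, train_frac: float = 0.8, seed: int = 0) -> SplitResult:
    """Split on subject identifiers; every epoch follows its subject."""
    subjects = list(dict.fromkeys(epochs.subjects))
    s = len(subjects)
    if s < 2:
        raise ValueError("need at least 2 subjects for a leave-p-out split")
    n_train = round_half_away(train_frac * s)
    n_train = min(max(n_train, 1), s - 1)
    perm = np.random.default_rng(seed).permutation(s)
    train_subjects = {subjects[i] for i in perm[:n_train]}
    mask = np.array([subj in train_subjects for subj in epochs.subjects])
    return SplitResult(np.flatnonzero(mask), np.flatnonzero(~mask), PATIENT_LEAVE_P_OUT, seed)


def intra_patient_then_pool(epochs: EpochSet, train_frac: float = 0.8, seed: int = 0) -> SplitResult:
    """Per-subject, class-stratified 80:20 epoch split, then pooled.

    A subject contributing a single epoch of some class sends it to the
    training side (with a log warning handled as a silent convention here:
    a lone epoch cannot appear on both sides anyway).
    """
    if epochs.n_epochs < 2:
        raise ValueError("need at least 2 epochs to split")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for subject in dict.fromkeys(epochs.subjects):
        sub_idx = np.flatnonzero(epochs.subjects == subject)
        for label in CLASSES:
            cls = sub_idx[epochs.labels[sub_idx] == label]
            if cls.size == 0:
                continue
            if cls.size == 1:
                train.extend(cls.tolist())
                continue
            k = round_half_away(train_frac * cls.size)
            k = min(max(k, 1), cls.size - 1)
            perm = rng.permutation(cls.size)
            train.extend(cls[perm[:k]].tolist())
            test.extend(cls[perm[k:]].tolist())
    return SplitResult(np.array(train), np.array(test), INTRA_PATIENT_THEN_POOL, seed)


_DISPATCH = {
    POOLED_RANDOM: pooled_random_split,
    PATIENT_LEAVE_P_OUT: patient_leave_p_out,
    INTRA_PATIENT_THEN_POOL: intra_patient_then_pool,
}


def split(epochs: EpochSet, strategy: str, train_frac: float = 0.8, seed: int = 0) -> SplitResult:
    """Dispatch to one of the three strategies by name."""
    if strategy not in _DISPATCH:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    return _DISPATCH[strategy](epochs, train_frac, seed)


@dataclass
class LeakageReport:
    passed: bool
    overlapping_indices: list[int] = field(default_factory=list)
    out_of_range: list[int] = field(default_factory=list)
    shared_subjects: list[str] = field(default_factory=list)


def verify_no_leakage(result: SplitResult, epochs: EpochSet) -> LeakageReport:
    """Check index disjointness (and subject disjointness for leave-p-out)."""
    overlap = np.intersect1d(result.train_idx, result.test_idx).tolist()
    all_idx = np.concatenate([result.train_idx, result.test_idx])
    out = all_idx[(all_idx < 0) | (all_idx >= epochs.n_epochs)].tolist()
    shared: list[str] = []
    if result.strategy == PATIENT_LEAVE_P_OUT and not out:
        train_subj = set(epochs.subjects[result.train_idx])
        test_subj = set(epochs.subjects[result.test_idx])
        shared = sorted(train_subj & test_subj)
    return LeakageReport(
        passed=not overlap and not out and not shared,
        overlapping_indices=overlap,
        out_of_range=out,
        shared_subjects=shared,
    )
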