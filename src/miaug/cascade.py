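"""Cascade composition of augmentation stages with exact ratio control.

A cascade is an ordered list of 1–3 augmentation stages applied sequentially
to the same source epoch (stage 1's output feeds stage 2, and so on).  The
``ratio`` controls how many augmented epochs are generated: for a training
set of N epochs, ``round(ratio · N)`` generated epochs are appended, with
source epochs drawn class-stratified so the generated subset mirrors the
training class proportions within rounding.  The study design uses ratios
0.25, 0.5, 0.75 and 1.0 (written 1:0.25 … 1:1), but any positive value is
accepted.

Generative stages ("cvae"/"cgan") replace the current epoch with a model
sample of the same class; they require a trained generator in the stage's
``params["generator"]``.

The API accepts only the training partition — the test side is never
touchable from here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
import yaml

from . import generative
from .containers import SYNTHETIC_SUBJECT, CLASSES, EpochSet, round_half_away
from .transforms import ALL_METHOD_NAMES, GENERATIVE_NAMES, AugmenterSpec, make_augmenter

__all__ = ["CascadeSpec", "augment_training_set", "enumerate_cascades", "load_cascade_grid"]


@dataclass
class CascadeSpec:
    """Ordered stage list plus generated:original ratio and seed."""

    stages: list[AugmenterSpec]
    ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.stages = [s if isinstance(s, AugmenterSpec) else AugmenterSpec(**s) for s in self.stages]
        if not 1 <= len(self.stages) <= 3:
            raise ValueError("a cascade has between 1 and 3 stages")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


def _stratified_sources(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Choose k source indices with class proportions matching ``labels``.

    Largest-remainder apportionment fixes the per-class counts; within a
    class, sampling is without replacement (with replacement only when a
    class must contribute more epochs than it has).
    """
    n = labels.size
    present = [c for c in CLASSES if np.any(labels == c)]
    counts = np.array([np.sum(labels == c) for c in present], dtype=float)
    exact = k * counts / n
    base = np.floor(exact).astype(int)
    rem = k - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:rem]] += 1
    chosen: list[int] = []
    for c, kc in zip(present, base):
        pool = np.flatnonzero(labels == c)
        if kc == 0:
            continue
        replace = kc > pool.size
        chosen.extend(rng.choice(pool, size=kc, replace=replace).tolist())
    return np.array(chosen, dtype=int)


def augment_training_set(train: EpochSet, spec: CascadeSpec,
                         force_apply: bool = False) -> EpochSet:
    """Append ``round(ratio · N)`` cascade-generated epochs to the train set.

    Original epochs appear first, bit-identical and exactly once.  Each
    generated epoch inherits its source's label and subject (the subject
    becomes the synthetic sentinel once a generative stage has replaced the
    signal).  Deterministic given ``spec.seed``.
    """
    if train.n_epochs == 0:
        raise ValueError("training set is empty")
    k = round_half_away(spec.ratio * train.n_epochs)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xCA]))

    appliers = []
    for stage in spec.stages:
        if stage.name in GENERATIVE_NAMES:
            gen = stage.params.get("generator")
            if gen is None:
                raise ValueError(
                    f"stage {stage.name!r} requires a trained generator in params['generator']"
                )
            appliers.append(("generative", gen))
        else:
            appliers.append(("transform", make_augmenter(stage, fs=train.fs, force_apply=force_apply)))

    sources = _stratified_sources(train.labels, k, rng)
    gen_data = np.empty((k, train.n_channels, train.n_samples), dtype=float)
    gen_labels = np.empty(k, dtype=object)
    gen_subjects = np.empty(k, dtype=object)
    for i, src in enumerate(sources):
        epoch = train.data[src]
        label = str(train.labels[src])
        subject = str(train.subjects[src])
        for kind, applier in appliers:
            if kind == "generative":
                epoch = generative.sample(applier, label, 1, seed=int(rng.integers(2**31))).data[0]
                subject = SYNTHETIC_SUBJECT
            else:
                epoch = applier(epoch, rng)
        gen_data[i] = epoch
        gen_labels[i] = label
        gen_subjects[i] = subject

    return EpochSet(
        data=np.concatenate([train.data.copy(), gen_data], axis=0),
        labels=np.concatenate([train.labels.copy(), gen_labels]),
        subjects=np.concatenate([train.subjects.copy(), gen_subjects]),
        fs=train.fs,
        channel_names=list(train.channel_names),
    )


def enumerate_cascades(operator_names: list[str] | tuple[str, ...] = ALL_METHOD_NAMES,
                       depth: int = 2, ratio: float = 1.0, seed: int = 0) -> list[CascadeSpec]:
    """All ordered tuples of distinct operators of the given depth.

    With n operators the count is the number of partial permutations
    P(n, depth) — e.g. 12 operators at depth 2 give 132 cascades.
    """
    if not 1 <= depth <= 3:
        raise ValueError("depth must be 1, 2 or 3")
    return [
        CascadeSpec(stages=[AugmenterSpec(name) for name in combo], ratio=ratio, seed=seed)
        for combo in permutations(operator_names, depth)
    ]


def load_cascade_grid(path: str | Path) -> list[CascadeSpec]:
    """Read a YAML grid file: a list of {stages, ratio, seed} entries.

    Each ``stages`` item is either an operator name or a {name, params}
    mapping.  Example::

        - stages: [dwt, gaussian_noise]
          ratio: 0.5
        - stages: [{name: sign_flip, params: {p: 0.3}}]
          ratio: 1.0
    """
    entries = yaml.safe_load(Path(path).read_text())
    specs = []
    for entry in entries:
        stages = [
            AugmenterSpec(s) if isinstance(s, str) else AugmenterSpec(s["name"], s.get("params", {}))
            for s in entry["stages"]
        ]
        specs.append(CascadeSpec(stages=stages, ratio=entry.get("ratio", 1.0), seed=entry.get("seed", 0)))
    return specs
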