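"""Apply the twelve augmentation operators and a cascade to a training set.

Each transformative operator maps one epoch to one augmented epoch; a
cascade chains up to three of them and controls how many augmented epochs
are appended per original (the 1:r ratio).
"""

import numpy as np

from miaug import AugmenterSpec, CascadeSpec, SyntheticSpec, augment_training_set, generate_dataset, make_augmenter
from miaug.transforms import OPERATOR_NAMES

ds = generate_dataset(SyntheticSpec(n_subjects=1, epochs_per_class_per_subject=10,
                                    n_channels=16, n_samples=160, seed=1))
epoch = ds.data[0]

print("single-operator effect on one epoch (relative RMS change, forced apply):")
for name in OPERATOR_NAMES:
    aug = make_augmenter(AugmenterSpec(name), fs=ds.fs, force_apply=True)
    out = aug(epoch, np.random.default_rng(0))
    rel = np.sqrt(np.mean((out - epoch) ** 2) / np.mean(epoch**2))
    print(f"  {name:18s} -> {rel:6.3f}")

# a two-stage cascade at ratio 1:0.5: 30 originals + 15 generated epochs
spec = CascadeSpec([AugmenterSpec("dwt"), AugmenterSpec("gaussian_noise")], ratio=0.5, seed=0)
augmented = augment_training_set(ds, spec)
print(f"\ncascade dwt+gaussian_noise at ratio 1:0.5: {ds.n_epochs} -> {augmented.n_epochs} epochs")
print("generated subset class counts:",
      {c: int(np.sum(augmented.labels[ds.n_epochs:] == c)) for c in ("LEFT", "RIGHT", "REST")})
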