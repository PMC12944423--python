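"""Build, inspect and train the EEGNet classifier on synthetic epochs.

The full-size architecture (64 channels x 640 samples) reduces the temporal
dimension 640 -> 160 -> 20 and feeds a 320-long flattened vector to the
output layer.  Training here uses a proportionally scaled variant so the
example finishes in seconds.
"""

import numpy as np

from miaug import EEGNetConfig, SyntheticSpec, build_model, generate_dataset, pooled_random_split, predict, shape_trace, train
from miaug.model import scaled_down_config

print("full-size EEGNet shape trace (64 ch x 640 samples):")
for name, shape in shape_trace(EEGNetConfig()).stages:
    print(f"  {name:22s} {shape}")

ds = generate_dataset(SyntheticSpec(n_channels=8, n_samples=128, seed=11))
sp = pooled_random_split(ds, seed=0)
train_set, test_set = ds.select(sp.train_idx), ds.select(sp.test_idx)

cfg = scaled_down_config(max_epochs=15, seed=0)
model = build_model(cfg)
result = train(model, train_set, cfg)
labels, _ = predict(model, test_set)
acc = float(np.mean(labels == test_set.labels))
print(f"\ntrained {len(result.loss_trace)} epochs "
      f"(loss {result.loss_trace[0]:.3f} -> {result.loss_trace[-1]:.3f}, "
      f"best epoch {result.best_epoch})")
print(f"held-out accuracy: {acc:.1%}  (chance level for 3 classes: 33.3%)")
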