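"""Round-trip a recording through EDF+ and run the preprocessing pipeline.

Writes a synthetic continuous recording with T0/T1/T2 cue annotations to an
EDF+ file, reads it back, excludes the standard electrode list, applies the
60 Hz notch, extracts fixed-length epochs at cue onsets and balances the
rest class — the same steps used to ingest real motor-imagery recordings.
"""

import tempfile
from pathlib import Path

import numpy as np

from miaug.dataio import (
    EXCLUDED_CHANNELS,
    PHYSIONET_CODE_MAP,
    RawRecording,
    balance_rest,
    exclude_channels,
    extract_epochs,
    notch_filter,
    read_edf,
    write_edf,
)

rng = np.random.default_rng(0)
fs = 160
names = ["C3", "C4", "CZ", "TP9", "O1", "O2"]  # TP9 is on the exclusion list
signal = rng.normal(0.0, 15.0, size=(len(names), fs * 60))
signal += 5.0 * np.sin(2 * np.pi * 60.0 * np.arange(signal.shape[1]) / fs)  # mains

cues = [(fs * t, 640, code) for t, code in
        [(2, "T0"), (8, "T1"), (14, "T2"), (20, "T0"), (26, "T1"), (32, "T0"), (38, "T2")]]
rec = RawRecording(signal, fs, names, cues)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "synthetic_run.edf"
    write_edf(path, rec)
    back = read_edf(path)
    print(f"read {path.name}: {back.signal.shape[0]} channels, "
          f"{back.signal.shape[1] / back.fs:.0f} s, {len(back.annotations)} annotations")

back = exclude_channels(back, EXCLUDED_CHANNELS)
print("after exclusion:", back.channel_names)

power_before = np.abs(np.fft.rfft(back.signal[0]))[60 * 60]  # 60 Hz bin of a 60 s record
back.signal = notch_filter(back.signal, 60.0, back.fs)
power_after = np.abs(np.fft.rfft(back.signal[0]))[60 * 60]
print(f"60 Hz component: {power_before:.0f} -> {power_after:.1f} (notch removes the mains line)")

epochs = extract_epochs(back, PHYSIONET_CODE_MAP, epoch_samples=640, subject_id="S001")
print("extracted epochs per class:", epochs.class_counts())
balanced = balance_rest(epochs, seed=0)
print("after rest balancing:  ", balanced.class_counts())
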