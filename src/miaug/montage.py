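"""Electrode naming for the 64-channel BCI2000-style 10–10 montage.

Only names are modelled — no electrode geometry or forward model.  The
synthetic generator needs named left/right sensorimotor groups so that
event-related desynchronization can be placed on the correct hemisphere,
and reduced-channel configurations need montages that still contain both
groups.
"""

from __future__ import annotations

#: The 64 channels of the BCI2000 acquisition montage (10–10 placement).
MONTAGE_64: list[str] = [
    "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "CZ", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6",
    "FP1", "FPZ", "FP2",
    "AF7", "AF3", "AFZ", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FT8", "T7", "T8", "T9", "T10", "TP7", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POZ", "PO4", "PO8",
    "O1", "OZ", "O2", "IZ",
]

#: Left-hemisphere sensorimotor electrode group (over the hand area).
LEFT_SM_GROUP: list[str] = ["C3", "C5", "C1", "CP3", "FC3"]

#: Right-hemisphere sensorimotor electrode group.
RIGHT_SM_GROUP: list[str] = ["C4", "C6", "C2", "CP4", "FC4"]

# Priority ordering used when fewer than 64 channels are requested: the
# sensorimotor strip first so that reduced montages keep both hemisphere
# groups, then midline, then the rest of the 10-10 set.
_PRIORITY: list[str] = (
    LEFT_SM_GROUP
    + RIGHT_SM_GROUP
    + ["CZ", "CPZ", "FCZ", "FC5", "FC6", "CP5", "CP6", "CP1", "CP2", "FC1", "FC2"]
)


def default_channel_names(n_channels: int) -> list[str]:
    """Channel names for an ``n_channels``-electrode synthetic montage.

    For 64 channels this is the standard acquisition order; for fewer, a
    subset that always includes the left and right sensorimotor groups.
    Above 64, generic ``CHxx`` names are appended.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_channels == 64:
        return list(MONTAGE_64)
    ordered = list(dict.fromkeys(_PRIORITY + MONTAGE_64))
    if n_channels <= len(ordered):
        return ordered[:n_channels]
    return ordered + [f"CH{i:02d}" for i in range(n_channels - len(ordered))]
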