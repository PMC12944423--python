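"""Synthetic three-class motor-imagery EEG generator.

The generator produces labeled epoch sets with the statistical structure the
rest of the pipeline assumes, so the whole benchmark can be exercised without
downloading any recordings.  Each epoch is built from three ingredients:

1. a 1/f^alpha ("pink") noise background on every channel, scaled by a
   per-subject, per-channel gain;
2. band-limited mu (8–12 Hz) and beta (18–26 Hz) sensorimotor rhythms on the
   left and right sensorimotor channel groups, with a smooth Hann envelope
   and a uniformly random phase per epoch; and
3. optionally a common-mode mains sinusoid (60 Hz, identical phase on all
   channels) so the notch-filter stage has something real to remove.

Class structure follows event-related desynchronization (ERD): imagining a
left-hand movement attenuates the mu/beta rhythm over the *contralateral*
(right) hemisphere group by the subject's ``erd_depth``, and vice versa; the
rest class leaves both hemispheres unattenuated.  This named-group
attenuation is the simplest testable surrogate for sensorimotor lateralization
— no volume conduction or leadfield modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import hann

from .containers import CLASSES, EpochSet
from .montage import LEFT_SM_GROUP, RIGHT_SM_GROUP, default_channel_names

__all__ = [
    "SubjectProfile",
    "SyntheticSpec",
    "make_subject_profiles",
    "generate_epoch",
    "generate_dataset",
]


@dataclass
class SubjectProfile:
    """Per-subject variability: channel gains, ERD depth and noise scale."""

    subject_id: str
    channel_gains: np.ndarray  # unitless positive multipliers, one per channel
    erd_depth: float  # fraction in [0, 1]: mu/beta attenuation during MI
    baseline_amp: float  # µV RMS of the 1/f background

    def __post_init__(self) -> None:
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if np.any(self.channel_gains <= 0):
            raise ValueError("channel_gains must all be positive")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.baseline_amp <= 0:
            raise ValueError("baseline_amp must be positive")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Defaults mirror the acquisition geometry of the 64-channel BCI2000-style
    setup: fs = 160 Hz and 640-sample (4 s) epochs.  Amplitudes are in µV.
    """

    n_subjects: int = 5
    epochs_per_class_per_subject: int = 20
    n_channels: int = 64
    n_samples: int = 640
    fs: float = 160.0
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (18.0, 26.0)
    mu_amp: float = 10.0
    beta_amp: float = 4.0
    line_freq: float = 60.0
    line_amp: float = 2.0
    noise_exponent: float = 1.0
    baseline_amp: float = 10.0
    gain_sigma: float = 0.1  # sigma of the log-normal channel-gain draw
    erd_range: tuple[float, float] = (0.7, 0.95)
    left_group: list[str] = field(default_factory=lambda: list(LEFT_SM_GROUP))
    right_group: list[str] = field(default_factory=lambda: list(RIGHT_SM_GROUP))
    channel_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.epochs_per_class_per_subject, self.n_channels, self.n_samples) < 1:
            raise ValueError("all counts must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for lo, hi in (self.mu_band, self.beta_band):
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError("oscillation bands must be ordered and below fs/2")
        if self.channel_names is None:
            self.channel_names = default_channel_names(self.n_channels)
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")

    def group_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the left/right sensorimotor groups present in the montage."""
        names = self.channel_names
        left = np.array([names.index(c) for c in self.left_group if c in names], dtype=int)
        right = np.array([names.index(c) for c in self.right_group if c in names], dtype=int)
        return left, right


def make_subject_profiles(
    n_subjects: int, rng_seed: int, spec: SyntheticSpec | None = None
) -> list[SubjectProfile]:
    """Draw ``n_subjects`` deterministic subject profiles.

    Channel gains are log-normal (``sigma = spec.gain_sigma``) independently
    per channel; ERD depth is uniform on ``spec.erd_range``; the background
    amplitude is log-normal around ``spec.baseline_amp``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    spec = spec if spec is not None else SyntheticSpec(n_subjects=n_subjects)
    rng = np.random.default_rng(rng_seed)
    profiles = []
    for i in range(n_subjects):
        gains = np.exp(rng.normal(0.0, spec.gain_sigma, size=spec.n_channels))
        erd = float(rng.uniform(*spec.erd_range))
        amp = float(spec.baseline_amp * np.exp(rng.normal(0.0, 0.15)))
        profiles.append(
            SubjectProfile(subject_id=f"S{i + 1:03d}", channel_gains=gains, erd_depth=erd, baseline_amp=amp)
        )
    return profiles


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise via spectral synthesis (random phases)."""
    freqs = np.fft.rfftfreq(n_samples)  # in cycles/sample; scale-free
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, freqs.size))
    spectrum = amp * np.exp(1j * phases)
    spectrum[:, 0] = 0.0
    if n_samples % 2 == 0:
        spectrum[:, -1] = spectrum[:, -1].real
    x = np.fft.irfft(spectrum, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms


def generate_epoch(
    label: str, profile: SubjectProfile, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Generate one ``(n_channels, n_samples)`` epoch in µV for ``label``.

    For LEFT the right-hemisphere group's rhythm amplitude is multiplied by
    ``1 - erd_depth`` (and symmetrically for RIGHT); REST is unattenuated.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASSES}")
    gains = profile.channel_gains
    if gains.shape != (spec.n_channels,):
        raise ValueError("profile channel_gains length does not match spec.n_channels")

    x = _pink_noise(rng, spec.n_channels, spec.n_samples, spec.noise_exponent)
    x *= profile.baseline_amp * gains[:, None]

    t = np.arange(spec.n_samples) / spec.fs
    env = hann(spec.n_samples, sym=False)
    left_idx, right_idx = spec.group_indices()
    attenuated = {"LEFT": "right", "RIGHT": "left", "REST": None}[label]

    for side, idx in (("left", left_idx), ("right", right_idx)):
        if idx.size == 0:
            continue
        for band, amp in ((spec.mu_band, spec.mu_amp), (spec.beta_band, spec.beta_amp)):
            f0 = rng.uniform(*band)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            a = amp * gains[idx]
            if side == attenuated:
                a = a * (1.0 - profile.erd_depth)
            x[idx] += a[:, None] * env[None, :] * np.sin(2.0 * np.pi * f0 * t + phase)[None, :]

    if spec.line_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        # common-mode mains coupling: identical phase and amplitude everywhere
        x += spec.line_amp * np.sin(2.0 * np.pi * spec.line_freq * t + phase)[None, :]
    return x


def generate_dataset(spec: SyntheticSpec) -> EpochSet:
    """Generate a balanced, deterministic dataset from ``spec``.

    Exactly ``epochs_per_class_per_subject`` epochs per (subject, class);
    the same spec (including seed) always yields bit-identical data.
    """
    profiles = make_subject_profiles(spec.n_subjects, spec.seed, spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xE6]))
    data, labels, subjects = [], [], []
    for profile in profiles:
        for label in CLASSES:
            for _ in range(spec.epochs_per_class_per_subject):
                data.append(generate_epoch(label, profile, spec, rng))
                labels.append(label)
                subjects.append(profile.subject_id)
    return EpochSet(
        data=np.stack(data),
        labels=np.array(labels, dtype=object),
        subjects=np.array(subjects, dtype=object),
        fs=spec.fs,
        channel_names=list(spec.channel_names),
    )


def background_only(spec: SyntheticSpec) -> SyntheticSpec:
    """Copy of ``spec`` with oscillations and mains off (pure 1/f background)."""
    return replace(spec, mu_amp=0.0, beta_amp=0.0, line_amp=0.0)
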