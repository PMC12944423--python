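"""Transformative augmentation operators for EEG epochs.

Each operator maps one ``(n_channels, n_samples)`` epoch to a new epoch of
the same shape, drawing any randomness from an explicit
``numpy.random.Generator`` so that a fixed seed reproduces the output
bit-for-bit.  Operators never modify their input in place.

Probability-gated operators (random masking, channels dropout, channel
shuffle, band stop at p = 0.5; sign flip at p = 0.3) interpret the gate as
"the transformation fires with probability p, otherwise the requested copy
passes through unchanged" — the cascade layer always receives exactly the
number of augmented copies it asked for, which keeps ratio control exact.

Default parameters:

============== ===========================================================
random_masking p = 0.5, contiguous segment of 10% of the samples zeroed
time_shift     cyclic shift, integer uniform on [-20, 20] samples
amplitude_scale one scalar factor uniform on (0.9, 1.1) for the whole epoch
gaussian_noise  additive noise, std = 0.05 × per-channel signal std
sign_flip      whole-epoch polarity inversion with p = 0.3
channels_dropout p = 0.5, 10% of channels zeroed for the whole epoch
channel_shuffle p = 0.5, uniform permutation of channel rows
band_stop      p = 0.5, Butterworth order 4, center U[10, 40] Hz,
               bandwidth U[1, 5] Hz, zero-phase forward–backward
dwt            db4 full-depth DWT, per-subband noise std = 0.05 × subband std
fourier_surrogate phase randomization with amplitude spectrum preserved
============== ===========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "AugmenterSpec",
    "OPERATOR_NAMES",
    "GENERATIVE_NAMES",
    "ALL_METHOD_NAMES",
    "make_augmenter",
    "random_masking",
    "time_shift",
    "amplitude_scale",
    "gaussian_noise",
    "sign_flip",
    "channels_dropout",
    "channel_shuffle",
    "band_stop",
    "dwt_augment",
    "fourier_surrogate",
]


# ---------------------------------------------------------------------------
# temporal domain


def random_masking(epoch: np.ndarray, rng: np.random.Generator, p: float = 0.5,
                   frac: float = 0.10, per_channel: bool = False, **_) -> np.ndarray:
    """Zero a contiguous segment of ``frac`` of the samples with probability p.

    By default the same segment is blanked on every channel (a global
    short-term artifact); ``per_channel=True`` draws one segment per channel.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("masking fraction must lie in (0, 1)")
    out = epoch.copy()
    if rng.random() >= p:
        return out
    n = epoch.shape[-1]
    length = int(np.floor(frac * n))
    if length == 0:
        return out
    if per_channel:
        for c in range(epoch.shape[0]):
            start = int(rng.integers(0, n - length + 1))
            out[c, start : start + length] = 0.0
    else:
        start = int(rng.integers(0, n - length + 1))
        out[:, start : start + length] = 0.0
    return out


def time_shift(epoch: np.ndarray, rng: np.random.Generator, max_shift: int = 20, **_) -> np.ndarray:
    """Cyclic shift by an integer k ~ U{-max_shift..max_shift}, all channels alike.

    ``out[c, t] = in[c, (t - k) mod n]`` — a positive k moves content later.
    """
    k = int(rng.integers(-max_shift, max_shift + 1))
    return np.roll(epoch, k, axis=-1)


def amplitude_scale(epoch: np.ndarray, rng: np.random.Generator,
                    lo: float = 0.9, hi: float = 1.1, **_) -> np.ndarray:
    """Multiply the whole epoch by one scalar drawn uniformly from (lo, hi)."""
    if lo > hi:
        raise ValueError("scale range must be ordered")
    return epoch * float(rng.uniform(lo, hi))


def gaussian_noise(epoch: np.ndarray, rng: np.random.Generator, factor: float = 0.05, **_) -> np.ndarray:
    """Add zero-mean Gaussian noise with std = factor × per-channel signal std."""
    if factor < 0:
        raise ValueError("noise factor must be >= 0")
    if factor == 0.0:
        return epoch.copy()
    sd = epoch.std(axis=-1, keepdims=True)
    return epoch + rng.normal(0.0, 1.0, size=epoch.shape) * (factor * sd)


def sign_flip(epoch: np.ndarray, rng: np.random.Generator, p: float = 0.3, **_) -> np.ndarray:
    """Invert the polarity of the entire epoch with probability p."""
    if rng.random() < p:
        return -epoch
    return epoch.copy()


# ---------------------------------------------------------------------------
# spatial domain


def channels_dropout(epoch: np.ndarray, rng: np.random.Generator, p: float = 0.5,
                     frac: float = 0.10, **_) -> np.ndarray:
    """Zero ``floor(frac · n_channels)`` randomly chosen channels with probability p."""
    if not 0.0 < frac < 1.0:
        raise ValueError("dropout fraction must lie in (0, 1)")
    out = epoch.copy()
    if rng.random() >= p:
        return out
    k = int(np.floor(frac * epoch.shape[0]))
    if k:
        drop = rng.choice(epoch.shape[0], size=k, replace=False)
        out[drop] = 0.0
    return out


def channel_shuffle(epoch: np.ndarray, rng: np.random.Generator, p: float = 0.5, **_) -> np.ndarray:
    """Permute channel rows uniformly with probability p (row contents untouched)."""
    if rng.random() >= p:
        return epoch.copy()
    return epoch[rng.permutation(epoch.shape[0])].copy()


# ---------------------------------------------------------------------------
# frequency / wavelet domain


def band_stop(epoch: np.ndarray, rng: np.random.Generator, p: float = 0.5,
              center_range: tuple[float, float] = (10.0, 40.0),
              bw_range: tuple[float, float] = (1.0, 5.0),
              order: int = 4, fs: float = 160.0, **_) -> np.ndarray:
    """Random zero-phase Butterworth band-stop filter, applied with probability p.

    Center and bandwidth are drawn uniformly from their ranges; a draw whose
    upper edge would reach Nyquist is clipped just below it (cannot happen
    with the default ranges at fs = 160 Hz).
    """
    out = epoch.copy()
    gate = rng.random()
    f0 = float(rng.uniform(*center_range))
    bw = float(rng.uniform(*bw_range))
    if gate >= p:
        return out
    lo, hi = f0 - bw / 2.0, f0 + bw / 2.0
    hi = min(hi, fs / 2.0 - 1.0)
    if lo <= 0 or lo >= hi:
        return out
    sos = butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")
    return sosfiltfilt(sos, out, axis=-1)


def dwt_augment(epoch: np.ndarray, rng: np.random.Generator, wavelet: str = "db4",
                factor: float = 0.05, **_) -> np.ndarray:
    """Perturb wavelet coefficients with Gaussian noise and reconstruct.

    Per channel: full-depth DWT (db4, periodization mode so the transform is
    orthonormal), add zero-mean noise with std = factor × the std of each
    subband's coefficients, inverse transform.  factor = 0 reduces to
    perfect reconstruction.
    """
    if factor < 0:
        raise ValueError("wavelet noise factor must be >= 0")
    n = epoch.shape[-1]
    w = pywt.Wavelet(wavelet)
    level = pywt.dwt_max_level(n, w.dec_len)
    out = np.empty_like(epoch, dtype=float)
    for c in range(epoch.shape[0]):
        coeffs = pywt.wavedec(epoch[c], w, mode="periodization", level=level)
        if factor > 0:
            coeffs = [band + rng.normal(0.0, 1.0, size=band.shape) * (factor * band.std())
                      for band in coeffs]
        rec = pywt.waverec(coeffs, w, mode="periodization")
        out[c] = rec[:n]
    return out


def fourier_surrogate(epoch: np.ndarray, rng: np.random.Generator, **_) -> np.ndarray:
    """Phase-randomized surrogate: amplitude spectrum kept, phases i.i.d. U(0, 2π).

    The DC bin (signal mean) and, for even lengths, the Nyquist bin are left
    untouched so the output is exactly real.
    """
    n = epoch.shape[-1]
    spec = np.fft.rfft(epoch, axis=-1)
    nbins = spec.shape[-1]
    hi = nbins - 1 if n % 2 == 0 else nbins  # exclude the real Nyquist bin for even n
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(epoch.shape[0], hi - 1))
    spec[:, 1:hi] = np.abs(spec[:, 1:hi]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n, axis=-1)


# ---------------------------------------------------------------------------
# registry


_REGISTRY: dict[str, Callable[..., np.ndarray]] = {
    "random_masking": random_masking,
    "time_shift": time_shift,
    "amplitude_scale": amplitude_scale,
    "gaussian_noise": gaussian_noise,
    "sign_flip": sign_flip,
    "channels_dropout": channels_dropout,
    "channel_shuffle": channel_shuffle,
    "band_stop": band_stop,
    "dwt": dwt_augment,
    "fourier_surrogate": fourier_surrogate,
}

#: Names of the ten transformative operators.
OPERATOR_NAMES: tuple[str, ...] = tuple(_REGISTRY)

#: Names of the two generative augmenters (handled by the cascade layer).
GENERATIVE_NAMES: tuple[str, ...] = ("cvae", "cgan")

#: All twelve augmentation methods.
ALL_METHOD_NAMES: tuple[str, ...] = OPERATOR_NAMES + GENERATIVE_NAMES

# Operators whose application is gated by a probability parameter ``p``.
_GATED = {"random_masking", "sign_flip", "channels_dropout", "channel_shuffle", "band_stop"}


@dataclass
class AugmenterSpec:
    """Declarative description of one augmentation operator.

    ``params`` overrides the operator's defaults; anything omitted keeps the
    documented default value.  Generative stages ("cvae"/"cgan") carry the
    trained generator under ``params["generator"]``.
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ALL_METHOD_NAMES:
            raise ValueError(f"unknown augmenter {self.name!r}; known: {ALL_METHOD_NAMES}")
        p = self.params.get("p")
        if p is not None and not 0.0 <= p <= 1.0:
            raise ValueError("probability p must lie in [0, 1]")


def make_augmenter(spec: AugmenterSpec, fs: float | None = None,
                   force_apply: bool = False) -> Callable[[np.ndarray, np.random.Generator], np.ndarray]:
    """Build ``f(epoch, rng) -> epoch`` from a spec (transformative ops only)."""
    if spec.name in GENERATIVE_NAMES:
        raise ValueError("generative stages are composed by the cascade layer, not make_augmenter")
    func = _REGISTRY[spec.name]
    params = dict(spec.params)
    if fs is not None and spec.name == "band_stop":
        params.setdefault("fs", fs)
    if force_apply and spec.name in _GATED:
        params["p"] = 1.0

    def apply(epoch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return func(epoch, rng, **params)

    return apply
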