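"""The ten transformative augmenters: parameters, oracles and purity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from miaug.transforms import (
    ALL_METHOD_NAMES,
    OPERATOR_NAMES,
    AugmenterSpec,
    amplitude_scale,
    band_stop,
    channel_shuffle,
    channels_dropout,
    dwt_augment,
    fourier_surrogate,
    gaussian_noise,
    make_augmenter,
    random_masking,
    sign_flip,
    time_shift,
)

GATED = {"random_masking", "sign_flip", "channels_dropout", "channel_shuffle", "band_stop"}


def rand_epoch(rng, c=6, t=64):
    return rng.normal(size=(c, t))


# ---------------------------------------------------------------------------
# shared contracts


@pytest.mark.parametrize("name", OPERATOR_NAMES)
def test_shape_purity_and_determinism(name, rng):
    """Every operator preserves shape, copies out, and is seed-reproducible."""
    epoch = rand_epoch(rng)
    original = epoch.copy()
    aug = make_augmenter(AugmenterSpec(name), fs=160.0)
    out1 = aug(epoch, np.random.default_rng(7))
    out2 = aug(epoch, np.random.default_rng(7))
    assert out1.shape == epoch.shape
    assert np.array_equal(epoch, original), f"{name} modified its input"
    assert np.array_equal(out1, out2), f"{name} not reproducible under a fixed seed"
    assert out1 is not epoch


@pytest.mark.parametrize("name", sorted(GATED))
@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_gated_operators_are_identity_at_p_zero(name, seed):
    rng_data = np.random.default_rng(seed)
    epoch = rand_epoch(rng_data)
    aug = make_augmenter(AugmenterSpec(name, {"p": 0.0}), fs=160.0)
    assert np.array_equal(aug(epoch, np.random.default_rng(seed)), epoch)


# ---------------------------------------------------------------------------
# temporal domain


class TestRandomMasking:
    def test_masked_segment_length_and_contiguity(self):
        epoch = np.ones((4, 640))
        out = random_masking(epoch, np.random.default_rng(0), p=1.0)
        for row in out:
            zeros = np.flatnonzero(row == 0)
            assert zeros.size == 64  # floor(0.10 * 640)
            assert zeros[-1] - zeros[0] == 63  # one contiguous run
        # same segment on every channel
        assert len({tuple(np.flatnonzero(r == 0)) for r in out}) == 1

    def test_per_channel_mode_draws_independent_segments(self):
        out = random_masking(np.ones((8, 640)), np.random.default_rng(0), p=1.0, per_channel=True)
        starts = {np.flatnonzero(r == 0)[0] for r in out}
        assert len(starts) > 1

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            random_masking(np.ones((2, 10)), np.random.default_rng(0), frac=1.5)


class TestTimeShift:
    def test_cyclic_definition(self):
        epoch = np.array([[1.0, 2.0, 3.0, 4.0]])
        rolled = np.roll(epoch, 1, axis=-1)
        assert rolled.tolist() == [[4.0, 1.0, 2.0, 3.0]]
        out = time_shift(epoch, np.random.default_rng(0), max_shift=0)
        assert np.array_equal(out, epoch)  # k = 0 is the identity

    def test_shift_range_is_inclusive_and_exhaustive(self):
        rng = np.random.default_rng(0)
        base = np.arange(64.0)[None, :]
        seen = set()
        for _ in range(4000):
            out = time_shift(base, rng)
            k = int(out[0, 0])  # value at t=0 is 64 - k mod 64
            seen.add((-k) % 64 if k else 0)
        shifts = {s if s <= 20 else s - 64 for s in seen}
        assert shifts == set(range(-20, 21))


class TestAmplitudeScale:
    def test_scale_within_range(self, rng):
        epoch = rand_epoch(rng)
        out = amplitude_scale(epoch, np.random.default_rng(0))
        ratio = out.std() / epoch.std()
        assert 0.9 < ratio < 1.1

    def test_degenerate_range_is_identity(self, rng):
        epoch = rand_epoch(rng)
        assert np.array_equal(amplitude_scale(epoch, np.random.default_rng(0), lo=1.0, hi=1.0), epoch)

    def test_zero_epoch_stays_zero(self):
        assert not amplitude_scale(np.zeros((3, 8)), np.random.default_rng(0)).any()


class TestGaussianNoise:
    def test_noise_factor_calibration(self):
        """Pooled std of the perturbation is 5% of the signal std."""
        rng = np.random.default_rng(0)
        num = den = 0.0
        for _ in range(300):
            epoch = rng.normal(size=(4, 64))
            out = gaussian_noise(epoch, rng)
            num += np.sum((out - epoch) ** 2)
            den += np.sum(epoch**2)
        assert np.sqrt(num / den) == pytest.approx(0.05, rel=0.02)

    def test_zero_factor_is_identity(self, rng):
        epoch = rand_epoch(rng)
        assert np.array_equal(gaussian_noise(epoch, np.random.default_rng(0), factor=0.0), epoch)

    def test_noise_is_zero_mean(self):
        rng = np.random.default_rng(1)
        epoch = rng.normal(size=(4, 256))
        diffs = [gaussian_noise(epoch, rng) - epoch for _ in range(100)]
        mean = np.mean(diffs)
        sem = np.std(diffs) / np.sqrt(np.size(diffs))
        assert abs(mean) < 4 * sem


class TestSignFlip:
    def test_flip_is_exact_negation_and_involution(self, rng):
        epoch = rand_epoch(rng)
        out = sign_flip(epoch, np.random.default_rng(0), p=1.0)
        assert np.array_equal(out, -epoch)
        assert np.array_equal(sign_flip(out, np.random.default_rng(0), p=1.0), epoch)

    def test_empirical_flip_rate(self):
        rng = np.random.default_rng(0)
        epoch = np.ones((2, 16))
        n = 10_000
        flips = sum(np.array_equal(sign_flip(epoch, rng), -epoch) for _ in range(n))
        half_width = 2.576 * np.sqrt(0.3 * 0.7 / n)
        assert abs(flips / n - 0.3) < half_width


# ---------------------------------------------------------------------------
# spatial domain


class TestChannelsDropout:
    def test_exact_channel_count_and_untouched_rest(self):
        rng_d = np.random.default_rng(0)
        epoch = np.random.default_rng(1).normal(size=(64, 32))
        out = channels_dropout(epoch, rng_d, p=1.0)
        zero_rows = np.flatnonzero(~out.any(axis=1))
        assert zero_rows.size == 6  # floor(0.10 * 64)
        kept = np.setdiff1d(np.arange(64), zero_rows)
        assert np.array_equal(out[kept], epoch[kept])


class TestChannelShuffle:
    def test_rows_preserved_as_multiset(self, rng):
        epoch = rand_epoch(rng, c=12)
        out = channel_shuffle(epoch, np.random.default_rng(3), p=1.0)
        assert not np.array_equal(out, epoch)
        assert np.array_equal(np.sort(out, axis=0), np.sort(epoch, axis=0))


# ---------------------------------------------------------------------------
# frequency / wavelet domain


class TestBandStop:
    fs = 160.0
    t = np.arange(int(fs * 4)) / fs

    def _forced(self, f0, bw):
        return dict(p=1.0, center_range=(f0, f0), bw_range=(bw, bw), fs=self.fs)

    def test_in_band_attenuation_fft_oracle(self):
        sine = np.sin(2 * np.pi * 20.0 * self.t)[None, :]
        out = band_stop(sine, np.random.default_rng(0), **self._forced(20.0, 4.0))
        amp_in = np.abs(np.fft.rfft(sine[0]))
        amp_out = np.abs(np.fft.rfft(out[0]))
        k = int(round(20.0 * sine.shape[-1] / self.fs))
        assert amp_out[k] < 0.10 * amp_in[k]
        assert np.sqrt(np.mean(out**2)) < 0.10 * np.sqrt(np.mean(sine**2))

    def test_out_of_band_preservation(self):
        sine = np.sin(2 * np.pi * 5.0 * self.t)[None, :]
        out = band_stop(sine, np.random.default_rng(0), **self._forced(20.0, 4.0))
        assert np.sqrt(np.mean(out**2)) == pytest.approx(np.sqrt(np.mean(sine**2)), rel=0.05)

    def test_zero_phase_via_cross_correlation(self):
        rng = np.random.default_rng(5)
        noise = rng.normal(size=(1, 640))
        out = band_stop(noise, np.random.default_rng(0), **self._forced(25.0, 5.0))
        xc = np.correlate(out[0] - out.mean(), noise[0] - noise.mean(), mode="full")
        assert int(np.argmax(xc)) == noise.shape[-1] - 1  # peak at lag 0


class TestDWT:
    def test_perfect_reconstruction_at_zero_factor(self, rng):
        for t in (64, 130, 640):  # even, non-dyadic odd, full length
            epoch = rng.normal(size=(3, t))
            out = dwt_augment(epoch, np.random.default_rng(0), factor=0.0)
            assert out.shape == epoch.shape
            rel = np.sqrt(np.mean((out - epoch) ** 2) / np.mean(epoch**2))
            assert rel < 1e-8

    def test_perturbation_magnitude_parseval_oracle(self):
        """Orthonormal wavelet: coefficient noise energy maps 1:1 to signal
        energy, so the relative RMS perturbation is ~the noise factor."""
        rng = np.random.default_rng(0)
        num = den = 0.0
        for _ in range(50):
            epoch = rng.normal(size=(2, 256))
            out = dwt_augment(epoch, rng)
            num += np.sum((out - epoch) ** 2)
            den += np.sum(epoch**2)
        rel = np.sqrt(num / den)
        assert 0.05 / 2 < rel < 0.05 * 2


class TestFourierSurrogate:
    def test_amplitude_spectrum_preserved(self, rng):
        for t in (64, 101):
            epoch = rng.normal(size=(4, t))
            out = fourier_surrogate(epoch, np.random.default_rng(0))
            a_in = np.abs(np.fft.rfft(epoch, axis=-1))
            a_out = np.abs(np.fft.rfft(out, axis=-1))
            assert np.max(np.abs(a_in - a_out)) < 1e-9 * np.max(a_in)

    def test_output_is_real_and_mean_preserved(self, rng):
        epoch = rand_epoch(rng) + 3.0
        out = fourier_surrogate(epoch, np.random.default_rng(0))
        assert np.isrealobj(out)
        assert np.allclose(out.mean(axis=-1), epoch.mean(axis=-1), atol=1e-9)

    def test_phases_actually_randomized(self, rng):
        epoch = rand_epoch(rng)
        out = fourier_surrogate(epoch, np.random.default_rng(0))
        assert not np.allclose(out, epoch, atol=1e-3)


# ---------------------------------------------------------------------------
# registry and specs


def test_registry_contents():
    assert len(OPERATOR_NAMES) == 10
    assert len(ALL_METHOD_NAMES) == 12
    assert set(ALL_METHOD_NAMES) - set(OPERATOR_NAMES) == {"cvae", "cgan"}


def test_spec_validation():
    with pytest.raises(ValueError):
        AugmenterSpec("warp")
    with pytest.raises(ValueError):
        AugmenterSpec("sign_flip", {"p": 1.5})


def test_force_apply_overrides_gate(rng):
    epoch = rand_epoch(rng)
    aug = make_augmenter(AugmenterSpec("sign_flip", {"p": 0.0}), force_apply=True)
    assert np.array_equal(aug(epoch, np.random.default_rng(0)), -epoch)


def test_generative_names_not_buildable_here():
    with pytest.raises(ValueError):
        make_augmenter(AugmenterSpec("cvae"))
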