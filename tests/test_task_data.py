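"""Data generators: Gray-Scott PDE, noise corruption, morph task, shapes."""

import numpy as np
import pytest

from ncalab import (
    GrayScottParams,
    MorphTaskSpec,
    NoiseSpec,
    corrupt_with_noise,
    gray_scott_rhs,
    make_initial_condition,
    make_morph_sequence,
    rotate_trajectory,
    simulate_gray_scott,
    synthetic_shapes,
)
from ncalab.training import TrainingData

from conftest import brute_force_correlate


class TestGrayScottRHS:
    def test_uniform_one_zero_is_fixed_point(self):
        p = GrayScottParams()
        dA, dB = gray_scott_rhs(np.ones((8, 8)), np.zeros((8, 8)), p)
        np.testing.assert_array_equal(dA, 0.0)
        np.testing.assert_array_equal(dB, 0.0)

    def test_uniform_fields_match_scalar_kinetics(self):
        p = GrayScottParams()
        a, b = 0.7, 0.3
        dA, dB = gray_scott_rhs(np.full((6, 6), a), np.full((6, 6), b), p)
        np.testing.assert_allclose(dA, -a * b**2 + p.alpha * (1 - a), atol=1e-12)
        np.testing.assert_allclose(dB, a * b**2 - (p.gamma + p.alpha) * b, atol=1e-12)

    def test_reaction_and_diffusion_cancel_globally(self, rng):
        p = GrayScottParams(alpha=0.0, gamma=0.0)
        dA, dB = gray_scott_rhs(rng.random((10, 10)), rng.random((10, 10)), p)
        assert abs((dA + dB).sum()) < 1e-10

    def test_unstable_timestep_rejected(self):
        with pytest.raises(ValueError):
            GrayScottParams(D_A=0.5, dt=1.0)


class TestSimulate:
    def test_uniform_initial_state_stays_constant(self):
        p = GrayScottParams(S=8, steps=16)
        data = simulate_gray_scott(np.ones((8, 8)), np.zeros((8, 8)), p, sample_every=4)
        np.testing.assert_allclose(data.y[..., 0], 1.0)
        np.testing.assert_allclose(data.y[..., 1], 0.0)

    def test_single_euler_step_matches_hand_rolled_oracle(self, rng):
        p = GrayScottParams(S=3, steps=1)
        A0, B0 = rng.random((3, 3)), rng.random((3, 3))
        data = simulate_gray_scott(A0, B0, p, sample_every=1)
        lapA = brute_force_correlate(A0, np.array([[1, 2, 1], [2, -12, 2], [1, 2, 1]]) / 4.0, "periodic")
        lapB = brute_force_correlate(B0, np.array([[1, 2, 1], [2, -12, 2], [1, 2, 1]]) / 4.0, "periodic")
        expA = A0 + p.D_A * lapA - A0 * B0**2 + p.alpha * (1 - A0)
        expB = B0 + p.D_B * lapB + A0 * B0**2 - (p.gamma + p.alpha) * B0
        np.testing.assert_allclose(data.y[1, 0, ..., 0], expA, atol=1e-12)
        np.testing.assert_allclose(data.y[1, 0, ..., 1], expB, atol=1e-12)

    def test_mass_conserved_without_kinetics(self, rng):
        p = GrayScottParams(alpha=0.0, gamma=0.0, S=16, steps=100)
        A0, B0 = rng.random((16, 16)), rng.random((16, 16))
        data = simulate_gray_scott(A0, B0, p, sample_every=1)
        total = data.y.sum(axis=(2, 3, 4))[:, 0]
        np.testing.assert_allclose(total, total[0], rtol=1e-9)

    def test_printed_rates_produce_patterning(self):
        """The maze-pattern rates leave a spatially structured B field."""
        p = GrayScottParams(S=32, steps=1024)
        A0, B0 = make_initial_condition("blobs", 32, seed=0)
        data = simulate_gray_scott(A0, B0, p, sample_every=256)
        assert data.y[-1, 0, ..., 1].std() > 0.05


class TestInitialConditions:
    def test_deterministic_under_seed(self):
        a1 = make_initial_condition("blobs", 24, seed=5)
        a2 = make_initial_condition("blobs", 24, seed=5)
        np.testing.assert_array_equal(a1[0], a2[0])
        np.testing.assert_array_equal(a1[1], a2[1])

    def test_blobs_structure(self):
        A, B = make_initial_condition("blobs", 32, seed=1)
        assert np.all(A[B == 0] == 1.0)
        assert B.max() > 0

    def test_high_frequency_spectral_content(self):
        """At least 10% of the B field's spectral energy sits above half the
        Nyquist band, verified by direct FFT."""
        _, B = make_initial_condition("high_frequency", 32, seed=2)
        F = np.abs(np.fft.fft2(B - B.mean())) ** 2
        freq = np.fft.fftfreq(32)
        fi, fj = np.meshgrid(freq, freq, indexing="ij")
        high = np.maximum(np.abs(fi), np.abs(fj)) > 0.25  # half-Nyquist
        assert F[high].sum() / F.sum() > 0.10

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_initial_condition("vortices", 16)


class TestNoise:
    def _data(self, rng, lo=0.0, hi=1.0):
        y = rng.uniform(lo, hi, size=(3, 1, 8, 8, 2))
        return TrainingData(y=y, t=1)

    def test_zero_intensity_is_identity(self, rng):
        data = self._data(rng)
        out = corrupt_with_noise(data, NoiseSpec(xi=0.0, seed=1))
        np.testing.assert_array_equal(out.y, data.y)
        assert out.y is not data.y

    def test_pure_noise_moments(self):
        y = np.zeros((2, 1, 100, 100, 5))
        y[0, 0, 0, 0, 0] = 1.0  # fixes (min, max) = (0, 1)
        data = TrainingData(y=y, t=1)
        out = corrupt_with_noise(data, NoiseSpec(xi=1.0, seed=3))
        assert out.y.min() >= 0.0 and out.y.max() <= 1.0
        n = out.y.size
        sigma = np.sqrt(1.0 / 12.0 / n)
        assert abs(out.y.mean() - 0.5) < 3 * sigma

    def test_half_intensity_on_zero_signal(self):
        y = np.zeros((2, 1, 50, 50, 1))
        y[0, 0, 0, 0, 0] = 1.0
        data = TrainingData(y=y, t=1)
        out = corrupt_with_noise(data, NoiseSpec(xi=0.5, seed=4))
        zero_signal = out.y[data.y == 0.0]  # these become 0.5 * U(0, 1)
        assert zero_signal.min() >= 0.0
        assert zero_signal.max() <= 0.5 + 1e-12
        assert np.all(data.y[1:] == 0)  # input untouched


class TestMorph:
    def _spec(self, **kw):
        imgs = synthetic_shapes(["disc", "cross", "star"], size=48, seed=0)
        defaults = dict(images=imgs, resolution=24, pad=4, R=2, shift_max=2,
                        repeat_final=2, noise_amplitude=0.0, t=8, seed=1)
        defaults.update(kw)
        return MorphTaskSpec(**defaults)

    def test_repeat_final_frame_count(self):
        data = make_morph_sequence(self._spec())
        assert data.M == 3  # 3 images + repeated final -> 4 transitions' frames
        np.testing.assert_array_equal(data.y[-1], data.y[-2])

    def test_unshifted_copy_embeds_image_exactly(self):
        data = make_morph_sequence(self._spec(R=1, shift_max=0))
        frame = data.y[0, 0]
        assert np.all(frame[0] == 0) and np.all(frame[:, -1] == 0)
        inner = frame[4:28, 4:28]
        imgs = synthetic_shapes(["disc", "cross", "star"], size=48, seed=0)
        down = imgs[0].reshape(24, 2, 24, 2, 4).mean(axis=(1, 3))
        np.testing.assert_allclose(inner, down, atol=1e-12)

    def test_shifted_copies_are_pure_translations(self):
        data = make_morph_sequence(self._spec(R=3, shift_max=2))
        a = data.y[0, 0, ..., 3]  # alpha channel, reference copy
        b = data.y[0, 1, ..., 3]
        # locate the shift via the cross-correlation peak
        corr = np.real(np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))))
        di, dj = np.unravel_index(np.argmax(corr), corr.shape)
        np.testing.assert_allclose(np.roll(b, (di, dj), axis=(0, 1)), a, atol=1e-12)

    def test_boundary_is_fixed_zero_with_noise(self):
        data = make_morph_sequence(self._spec(noise_amplitude=0.005))
        assert data.boundary == "fixed-zero"
        assert np.all(data.y[:, :, 0] == 0) and np.all(data.y[:, :, :, -1] == 0)

    def test_too_few_images_rejected(self):
        imgs = synthetic_shapes(["disc"], size=24, seed=0)
        with pytest.raises(ValueError):
            MorphTaskSpec(images=imgs, resolution=12, pad=2)


class TestShapes:
    def test_deterministic_bytes(self):
        a = synthetic_shapes(["disc", "star"], size=32, seed=7)
        b = synthetic_shapes(["disc", "star"], size=32, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_colour_support_matches_alpha(self):
        for img in synthetic_shapes(["disc", "ring", "cross", "star", "glider"], size=32):
            outside = img[..., 3] == 0
            assert np.all(img[outside, :3] == 0)
            assert set(np.unique(img[..., 3])) <= {0.0, 1.0}

    def test_distinct_kinds_differ(self):
        disc, cross = synthetic_shapes(["disc", "cross"], size=32, seed=0)
        assert np.linalg.norm(disc - cross) > 0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            synthetic_shapes(["triangle"], size=16)


class TestRotate:
    def _disc_data(self):
        img = synthetic_shapes(["disc"], size=32, seed=0)[0]
        y = np.zeros((2, 1, 32, 32, 4))
        y[:] = img
        return TrainingData(y=y, t=1)

    def test_full_turn_is_identity(self):
        data = self._disc_data()
        out = rotate_trajectory(data, 360.0)
        np.testing.assert_array_equal(out.y, data.y)

    def test_two_quarter_turns_equal_half_turn_exactly(self, rng):
        y = rng.random((2, 1, 8, 8, 3))
        data = TrainingData(y=y, t=1)
        twice = rotate_trajectory(rotate_trajectory(data, 90.0), 90.0)
        once = rotate_trajectory(data, 180.0)
        np.testing.assert_array_equal(twice.y, once.y)

    def test_offlattice_rotation_preserves_disc_mass(self):
        data = self._disc_data()
        out = rotate_trajectory(data, 45.0)
        m0 = data.y[0, 0, ..., 3].sum()
        m1 = out.y[0, 0, ..., 3].sum()
        assert abs(m1 - m0) / m0 <= 0.01
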