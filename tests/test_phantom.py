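"""Layered ultrasound phantom, noise model, and Fourier-domain simulator."""

import numpy as np
import pytest

from segdict import (
    NoiseSpec,
    PhantomSpec,
    add_gaussian_noise,
    make_central_mask,
    make_phantom,
    make_two_texture_phantom,
    psnr,
    simulate_kspace,
)
from segdict.phantom import LACUNA_LABEL


def test_noise_free_limit_is_piecewise_constant():
    spec = PhantomSpec(n_lacunae=0, seed=0)
    image, labels = make_phantom(spec, with_speckle=False)
    for layer, level in enumerate(spec.layer_echogenicity):
        member = labels == layer
        assert member.any()
        np.testing.assert_allclose(image[member], level)


def test_deterministic_given_seed():
    a_img, a_lab = make_phantom(PhantomSpec(seed=42))
    b_img, b_lab = make_phantom(PhantomSpec(seed=42))
    np.testing.assert_array_equal(a_img, b_img)
    np.testing.assert_array_equal(a_lab, b_lab)
    c_img, _ = make_phantom(PhantomSpec(seed=43))
    assert not np.array_equal(a_img, c_img)


def test_lacunae_are_anechoic_versus_muscle():
    """The fluid-filled lacunae must be darker than surrounding muscle in
    every realization."""
    for seed in range(20):
        image, labels = make_phantom(PhantomSpec(seed=seed))
        lacuna = image[labels == LACUNA_LABEL]
        muscle = image[labels == 3]
        assert lacuna.size > 0
        assert lacuna.mean() < muscle.mean()


def test_speckle_has_unit_mean_and_look_scaled_variance():
    spec = PhantomSpec(height=256, width=256, n_lacunae=0, seed=1)
    image, labels = make_phantom(spec)
    flat, _ = make_phantom(spec, with_speckle=False)
    ratio = image[labels == 3] / flat[labels == 3]
    assert ratio.mean() == pytest.approx(1.0, abs=0.05)
    # multi-look averaging: variance well below the 1-look value of 1
    assert ratio.var() < 0.6


def test_lacunae_must_fit_in_muscle_band():
    spec = PhantomSpec(
        height=40,
        layer_fractions=(0.3, 0.3, 0.3, 0.1),
        lacuna_radius_range=(3.0, 8.0),
    )
    with pytest.raises(ValueError, match="muscle band"):
        make_phantom(spec)


class TestGaussianNoise:
    def test_vanishing_variance_limit(self, rng):
        image = rng.random((32, 32)) + 0.5
        noisy = add_gaussian_noise(image, NoiseSpec(1e-12), seed=0)
        assert float(np.mean((noisy - image) ** 2)) < 1e-10 * image.max()

    def test_variance_matches_specification(self):
        """Sample variance of the added noise equals fraction * max."""
        image = np.full((400, 400), 100.0)
        noisy = add_gaussian_noise(image, NoiseSpec(0.01), seed=3)
        delta = noisy - image
        assert delta.mean() == pytest.approx(0.0, abs=4 * 1.0 / 400)
        assert delta.var() == pytest.approx(1.0, rel=0.05)

    def test_noise_is_gaussian(self):
        from scipy import stats

        image = np.full((1000, 1000), 10.0)
        delta = add_gaussian_noise(image, NoiseSpec(0.1), seed=9) - image
        assert abs(stats.skew(delta.ravel())) < 0.05

    def test_complex_noise_returns_magnitude(self):
        image = np.zeros((64, 64)) + 1.0
        noisy = add_gaussian_noise(image, NoiseSpec(0.05, complex_valued=True), seed=4)
        assert (noisy >= 0).all()
        # magnitude of a complex point is biased upward relative to its
        # real part alone
        assert noisy.mean() > 1.0

    def test_deterministic_and_validated(self):
        image = np.ones((8, 8))
        a = add_gaussian_noise(image, NoiseSpec(0.01), seed=5)
        b = add_gaussian_noise(image, NoiseSpec(0.01), seed=5)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            NoiseSpec(0.0)
        with pytest.raises(ValueError, match="positive"):
            add_gaussian_noise(np.zeros((4, 4)), NoiseSpec(0.01), seed=0)


class TestKspace:
    def test_full_mask_roundtrip(self, rng):
        image = rng.random((32, 32))
        mask = make_central_mask((32, 32), 1.0)
        kspace = simulate_kspace(image, mask)
        back = np.fft.ifft2(np.fft.ifftshift(kspace.samples), norm="ortho")
        np.testing.assert_allclose(back.real, image, atol=1e-10)

    def test_unmasked_entries_are_not_data(self, rng):
        image = rng.random((32, 32))
        mask = make_central_mask((32, 32), 0.15)
        kspace = simulate_kspace(image, mask)
        assert not kspace.samples[~mask.mask].any()

    def test_undersampling_causes_aliasing(self):
        image, _ = make_phantom(PhantomSpec(height=64, width=64, seed=2))
        full = simulate_kspace(image, make_central_mask((64, 64), 1.0))
        part = simulate_kspace(image, make_central_mask((64, 64), 0.15))
        rec_full = np.abs(np.fft.ifft2(np.fft.ifftshift(full.samples), norm="ortho"))
        rec_part = np.abs(np.fft.ifft2(np.fft.ifftshift(part.samples), norm="ortho"))
        assert psnr(image, rec_part, 1) < psnr(image, rec_full, 1)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            simulate_kspace(rng.random((16, 16)), make_central_mask((32, 32), 0.5))


class TestCentralMask:
    def test_full_fraction_selects_everything(self):
        assert make_central_mask((8, 8), 1.0).mask.all()

    def test_fifteen_percent_of_hundred_rows(self):
        mask = make_central_mask((100, 64), 0.15)
        rows = np.flatnonzero(mask.mask[:, 0])
        assert len(rows) == 15
        assert list(rows) == list(range(43, 58))  # symmetric about row 50

    def test_tiny_fraction_keeps_center_row(self):
        mask = make_central_mask((10, 10), 0.01)
        rows = np.flatnonzero(mask.mask[:, 0])
        assert list(rows) == [5]

    def test_even_count_favors_lower_index(self):
        mask = make_central_mask((10, 10), 0.2)  # 2 rows
        rows = np.flatnonzero(mask.mask[:, 0])
        assert list(rows) == [4, 5]

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            make_central_mask((10, 10), 0.0)
        with pytest.raises(ValueError):
            make_central_mask((10, 10), 1.2)


def test_two_texture_phantom_structure():
    image, partition = make_two_texture_phantom(seed=0)
    assert image.shape == partition.shape == (96, 96)
    assert set(np.unique(partition)) == {0, 1}
    a, b = make_two_texture_phantom(seed=3), make_two_texture_phantom(seed=3)
    np.testing.assert_array_equal(a[0], b[0])
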