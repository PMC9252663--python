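"""Synthetic layered-tissue ultrasound phantom and noise generators.

The phantom emulates a B-mode scan of a lower limb with edema: four
horizontal tissue bands from the probe down — skin (bright), fat-rich
subcutaneous tissue (darker), deep fascia (bright thin band) and muscle —
with anechoic (near-zero echo) elliptical lacunae inside the muscle
band standing in for fluid accumulation.  Texture comes from fully
developed multiplicative speckle, modelled per pixel as the mean of
``speckle_looks`` squared magnitudes of unit-variance circular complex
Gaussians (mean 1, variance ``1/speckle_looks``).

Measurement noise is additive zero-mean Gaussian whose *variance* is a
stated fraction of the image maximum; the complex variant adds
independent noise of that variance to the real and imaginary channels
and returns the magnitude, mimicking noise injected before envelope
detection.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import as_pixels

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "make_phantom",
    "add_gaussian_noise",
    "simulate_kspace",
    "make_two_texture_phantom",
    "NOISE_SWEEP_FRACTIONS",
]

#: The standard noise-sweep levels: variance as a fraction of the image max.
NOISE_SWEEP_FRACTIONS = (0.005, 0.01, 0.03, 0.05, 0.10)

#: Label given to lacunae in the ground-truth map (layers are 0..3).
LACUNA_LABEL = 4


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and echogenicity of the layered phantom.

    ``layer_fractions`` are the top-down height fractions of skin,
    subcutaneous tissue, deep fascia and muscle; anything left below the
    four bands is absorbed into the muscle band.  Echogenicities are
    base intensities in [0, 1].
    """

    height: int = 128
    width: int = 128
    layer_fractions: tuple[float, float, float, float] = (0.08, 0.22, 0.08, 0.62)
    layer_echogenicity: tuple[float, float, float, float] = (0.85, 0.40, 0.95, 0.55)
    n_lacunae: int = 4
    lacuna_radius_range: tuple[float, float] = (3.0, 8.0)
    speckle_looks: int = 4
    layer_psf_sigma: tuple[tuple[float, float], ...] = (
        (0.6, 0.6),  # skin: fine grain
        (1.8, 1.8),  # subcutaneous fat: coarse isotropic
        (1.0, 3.0),  # fascia: smooth, laterally smeared
        (0.7, 2.5),  # muscle: anisotropic, fibrous striation
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom must be at least 1x1")
        if len(self.layer_fractions) != 4 or len(self.layer_echogenicity) != 4:
            raise ValueError("exactly four layers are required")
        if any(f < 0 for f in self.layer_fractions) or sum(self.layer_fractions) > 1 + 1e-9:
            raise ValueError("layer fractions must be non-negative and sum to <= 1")
        if self.n_lacunae < 0:
            raise ValueError("n_lacunae must be >= 0")
        if self.speckle_looks < 1:
            raise ValueError("speckle_looks must be >= 1")
        lo, hi = self.lacuna_radius_range
        if not 0 < lo <= hi:
            raise ValueError("lacuna radius range must satisfy 0 < min <= max")
        if len(self.layer_psf_sigma) != 4:
            raise ValueError("one (axial, lateral) PSF width pair per layer required")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: variance = ``variance_fraction`` times the
    image maximum (times the squared maximum with
    ``variance_of_max_squared``, the alternative reading of the
    percent-of-maximum convention); ``complex_valued`` injects it on both
    quadrature channels and returns the magnitude."""

    variance_fraction: float
    complex_valued: bool = False
    variance_of_max_squared: bool = False

    def __post_init__(self) -> None:
        if self.variance_fraction <= 0:
            raise ValueError("variance_fraction must be > 0")


def _layer_rows(spec: PhantomSpec) -> list[tuple[int, int]]:
    """(start, stop) rows of the four bands; the muscle band takes the rest."""
    bounds = []
    top = 0
    for i, frac in enumerate(spec.layer_fractions):
        stop = top + int(round(frac * spec.height))
        if i == 3:
            stop = spec.height
        stop = min(stop, spec.height)
        bounds.append((top, stop))
        top = stop
    return bounds


def make_phantom(spec: PhantomSpec = PhantomSpec(), with_speckle: bool = True):
    """Generate the layered phantom.

    Returns
    -------
    (image, label_map)
        ``image`` is the clean (speckled but noise-free) float image;
        ``label_map`` holds the ground-truth region per pixel: layer
        index 0..3, lacunae labelled 4.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    base = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=int)
    bands = _layer_rows(spec)
    for i, (top, stop) in enumerate(bands):
        base[top:stop, :] = spec.layer_echogenicity[i]
        labels[top:stop, :] = i

    muscle_top, muscle_stop = bands[3]
    if spec.n_lacunae > 0:
        rmax = spec.lacuna_radius_range[1]
        if muscle_stop - muscle_top < 2 * rmax + 2:
            raise ValueError("muscle band too thin to contain the requested lacunae")
        if w < 2 * rmax + 2:
            raise ValueError("phantom too narrow to contain the requested lacunae")
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(spec.n_lacunae):
            ry = rng.uniform(*spec.lacuna_radius_range)
            rx = ry * rng.uniform(0.7, 1.4)
            rx = min(rx, (w - 2) / 2)
            cy = rng.uniform(muscle_top + ry + 1, muscle_stop - ry - 1)
            cx = rng.uniform(rx + 1, w - rx - 1)
            inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            base[inside] = 0.02  # anechoic: near-zero echo
            labels[inside] = LACUNA_LABEL

    if with_speckle:
        # Each tissue layer gets speckle with its own point-spread
        # function, so layers differ in texture (grain size, fiber
        # orientation) and not just brightness; lacunae inherit the
        # muscle texture at their near-zero echo level.
        speckle = np.empty((h, w))
        layer_of_pixel = np.where(labels == LACUNA_LABEL, 3, labels)
        for i, sigma in enumerate(spec.layer_psf_sigma):
            if not (layer_of_pixel == i).any():
                continue
            field_ = _speckle_field(rng, (h, w), spec.speckle_looks, sigma)
            speckle[layer_of_pixel == i] = field_[layer_of_pixel == i]
        image = base * speckle
    else:
        image = base.copy()
    return image, labels


def _speckle_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    looks: int,
    psf_sigma: tuple[float, float],
) -> np.ndarray:
    """Fully developed multi-look speckle with unit mean.

    Each look is the squared magnitude of a circular complex Gaussian
    scatterer field imaged through a Gaussian point-spread function of
    (axial, lateral) widths ``psf_sigma`` pixels (``(0, 0)`` gives
    pixel-iid speckle); the looks are averaged and the result
    normalized to unit mean, so variance is ``~1/looks`` and granules
    have the PSF's correlation lengths — as in a B-mode envelope image.
    """
    from scipy import ndimage

    intensity = np.zeros(shape)
    for _ in range(looks):
        field_ = (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        ) / np.sqrt(2.0)
        if max(psf_sigma) > 0:
            field_ = ndimage.gaussian_filter(field_.real, psf_sigma, mode="wrap") + (
                1j * ndimage.gaussian_filter(field_.imag, psf_sigma, mode="wrap")
            )
        intensity += np.abs(field_) ** 2
    intensity /= looks
    return intensity / intensity.mean()


def add_gaussian_noise(image, noise: NoiseSpec | float, seed: int = 0) -> np.ndarray:
    """Corrupt an image with the additive zero-mean Gaussian noise model.

    The noise variance equals ``variance_fraction * max(image)``; with
    ``complex_valued`` the image is treated as the real channel, noise of
    the same variance lands independently on the real and imaginary
    channels, and the magnitude is returned.
    """
    if not isinstance(noise, NoiseSpec):
        noise = NoiseSpec(float(noise))
    pixels = as_pixels(image)
    peak = float(pixels.max())
    if peak <= 0:
        raise ValueError("image maximum must be positive to scale the noise")
    scale = peak**2 if noise.variance_of_max_squared else peak
    sigma = float(np.sqrt(noise.variance_fraction * scale))
    rng = np.random.default_rng(seed)
    if noise.complex_valued:
        real = pixels + sigma * rng.standard_normal(pixels.shape)
        imag = sigma * rng.standard_normal(pixels.shape)
        return np.hypot(real, imag)
    return pixels + sigma * rng.standard_normal(pixels.shape)


def simulate_kspace(image, mask, noise: NoiseSpec | None = None, seed: int = 0):
    """Forward model for undersampled Fourier-domain acquisition.

    Takes the centered (zero frequency in the middle) orthonormal 2-D
    Fourier transform of the (optionally noise-corrupted) image and
    retains coefficients only where the mask is true.

    Returns a :class:`segdict.reconstruction.KSpaceData`.
    """
    from .reconstruction import KSpaceData, SamplingMask

    pixels = as_pixels(image)
    if not isinstance(mask, SamplingMask):
        mask = SamplingMask(np.asarray(mask, dtype=bool))
    if mask.mask.shape != pixels.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match image shape {pixels.shape}"
        )
    field_ = pixels.astype(complex)
    if noise is not None:
        peak = float(pixels.max())
        if peak <= 0:
            raise ValueError("image maximum must be positive to scale the noise")
        sigma = float(np.sqrt(noise.variance_fraction * peak))
        rng = np.random.default_rng(seed)
        field_ = field_ + sigma * (
            rng.standard_normal(pixels.shape) + 1j * rng.standard_normal(pixels.shape)
        )
    coeffs = np.fft.fftshift(np.fft.fft2(field_, norm="ortho"))
    samples = np.where(mask.mask, coeffs, 0.0 + 0.0j)
    return KSpaceData(samples=samples, mask=mask)


def make_two_texture_phantom(
    shape: tuple[int, int] = (96, 96), seed: int = 0, amplitude: float = 0.35
):
    """A piecewise-textured image for segmentation-recovery checks.

    The left half carries horizontal stripes, the right half vertical
    stripes (distinct oriented textures over a shared mean level), with
    mild per-seed frequency/phase jitter and a touch of Gaussian noise.

    Returns ``(image, partition)`` with ``partition`` 0 on the left and
    1 on the right.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    f_left = rng.uniform(0.8, 1.2) * 2.0 * np.pi / 6.0
    f_right = rng.uniform(0.8, 1.2) * 2.0 * np.pi / 6.0
    left = 0.5 + amplitude * np.sin(f_left * yy + rng.uniform(0, 2 * np.pi))
    right = 0.5 + amplitude * np.sin(f_right * xx + rng.uniform(0, 2 * np.pi))
    split = w // 2
    image = np.where(xx < split, left, right)
    image = image + 0.02 * rng.standard_normal(image.shape)
    partition = (xx >= split).astype(int)
    return image, partition
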