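"""The S-DL pipeline: cluster patches, train one dictionary per cluster,
sparse-code, reassemble — plus the undersampled-Fourier variant.

Denoising workflow
------------------
1. extract overlapping patches;
2. K-means the patches on standardized texture descriptors (patch mean,
   spread, and directional gradient energies — shift-insensitive
   statistics, so clusters capture texture families);
3. per cluster, K-SVD-train an overcomplete dictionary on that
   cluster's patches (clusters with fewer patches than atoms fall back
   to a single global dictionary, with a logged warning);
4. OMP-code each patch against its own cluster's dictionary and add the
   patch mean back;
5. reassemble by overlap averaging;
6. emit a label map: per pixel, the majority cluster among covering
   patches (ties to the lowest label).

Plain dictionary learning (DL) is the same pipeline with the clustering
stage skipped — literally S-DL with one cluster.

Undersampled reconstruction alternates an S-DL denoising pass with a
Fourier-domain data-consistency step: at sampled locations the
coefficient becomes ``(F(estimate) + nu * measured) / (1 + nu)``; the
weight ``nu`` balances the sparse-coding prior against fidelity to the
measured k-space samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .cluster import LloydKMeans
from .dictionary import Dictionary, ksvd_train, omp_encode
from .patches import PatchConfig, PatchSet, assemble_patches, extract_patches
from .raster import as_pixels

__all__ = [
    "SdlConfig",
    "SamplingMask",
    "KSpaceData",
    "LabelMap",
    "SDLDenoiser",
    "sdl_denoise",
    "dl_denoise",
    "sdl_reconstruct",
    "make_central_mask",
]

logger = logging.getLogger(__name__)

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class SdlConfig:
    """All tunables of the S-DL pipeline.

    Defaults follow common K-SVD denoising practice at desk scale: 8x8
    patches with stride 2, four texture clusters, 256 atoms per cluster,
    8-atom sparse codes, 10 K-SVD iterations.  ``residual_tol`` > 0
    switches OMP to noise-aware stopping (stop once the patch residual
    drops below it) with ``sparsity`` as a cap — the standard choice
    when the corruption level is known.
    """

    patch_size: int = 8
    stride: int = 2
    n_clusters: int = 4
    n_atoms: int = 256
    sparsity: int = 8
    ksvd_iters: int = 10
    outer_iters: int = 5
    nu: float = 100.0
    seed: int = 0
    residual_tol: float = 0.0

    def __post_init__(self) -> None:
        PatchConfig(self.patch_size, self.stride)  # validates geometry
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not self.patch_size**2 < self.n_atoms:
            raise ValueError(
                "per-cluster dictionary must be overcomplete: "
                f"patch_size**2={self.patch_size ** 2} must be < n_atoms={self.n_atoms}"
            )
        if not 0 <= self.sparsity <= self.n_atoms:
            raise ValueError("sparsity must be in [0, n_atoms]")
        if self.ksvd_iters < 0 or self.outer_iters < 1:
            raise ValueError("ksvd_iters must be >= 0 and outer_iters >= 1")
        if self.nu < 0:
            raise ValueError("nu must be >= 0")

    @property
    def patch_cfg(self) -> PatchConfig:
        return PatchConfig(self.patch_size, self.stride)


@dataclass
class SamplingMask:
    """Boolean Fourier-domain sampling pattern (centered layout)."""

    mask: np.ndarray
    center_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass
class KSpaceData:
    """Measured Fourier coefficients, defined only where the mask is true."""

    samples: np.ndarray
    mask: SamplingMask

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.shape != self.mask.mask.shape:
            raise ValueError("samples and mask shapes differ")
        # Coefficients outside the mask are not data; zero them so no
        # operation can read them.
        self.samples = np.where(self.mask.mask, self.samples, 0.0 + 0.0j)


@dataclass
class LabelMap:
    """Per-pixel integer cluster labels, same shape as the source image."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")


def _seed_for(base: int, stage: int) -> int:
    return int((base * 1_000_003 + stage) % (2**31 - 1))


def _patch_features(data: np.ndarray, patch_size: int) -> np.ndarray:
    """Per-patch texture descriptors used for the segmentation stage:
    (mean, standard deviation, lateral gradient energy, axial gradient
    energy).  Euclidean K-means on raw patch vectors cannot separate
    shift-invariant textures — two opposite-phase patches of the *same*
    texture lie farther apart than patches of different textures — so
    clustering runs on these shift-insensitive statistics instead.
    One row per patch."""
    p = patch_size
    blocks = data.T.reshape(-1, p, p)
    mean = data.mean(axis=0)
    std = data.std(axis=0)
    grad_x = np.abs(np.diff(blocks, axis=2)).mean(axis=(1, 2))
    grad_y = np.abs(np.diff(blocks, axis=1)).mean(axis=(1, 2))
    return np.stack([mean, std, grad_x, grad_y], axis=1)


class SDLDenoiser(BaseEstimator):
    """Segmentation dictionary learning denoiser (scikit-learn style).

    ``fit(image)`` clusters the image's patches and trains the
    per-cluster dictionaries; ``transform(image)`` sparse-codes patches
    with their cluster's dictionary and reassembles.  For the usual
    single-image use, :meth:`fit_transform` on the noisy image does both.

    Clustering runs on standardized per-patch texture features
    (:func:`_patch_features`); sparse coding always operates on the
    mean-subtracted patch vectors, with the patch mean added back after
    coding.

    Attributes (after fit)
    ----------------------
    kmeans_ : LloydKMeans or None
        The patch-clustering model (None when ``n_clusters == 1`` or the
        image has no texture).
    dictionaries_ : dict[int, Dictionary]
        Trained dictionary per cluster label (missing for degenerate or
        fallen-back clusters).
    global_dictionary_ : Dictionary or None
        Trained lazily when some cluster is too small to support its own.
    label_map_ : ndarray (after transform)
        Majority-vote cluster label per pixel.
    """

    def __init__(
        self,
        patch_size: int = 8,
        stride: int = 2,
        n_clusters: int = 4,
        n_atoms: int = 256,
        sparsity: int = 8,
        ksvd_iters: int = 10,
        residual_tol: float = 0.0,
        random_state: int = 0,
    ):
        self.patch_size = patch_size
        self.stride = stride
        self.n_clusters = n_clusters
        self.n_atoms = n_atoms
        self.sparsity = sparsity
        self.ksvd_iters = ksvd_iters
        self.residual_tol = residual_tol
        self.random_state = random_state

    def _config(self) -> SdlConfig:
        return SdlConfig(
            patch_size=self.patch_size,
            stride=self.stride,
            n_clusters=self.n_clusters,
            n_atoms=self.n_atoms,
            sparsity=self.sparsity,
            ksvd_iters=self.ksvd_iters,
            seed=self.random_state,
            residual_tol=self.residual_tol,
        )

    # -- fitting ---------------------------------------------------------

    def fit(self, image, y=None):
        cfg = self._config()
        pixels = as_pixels(image)
        patches = extract_patches(pixels, cfg.patch_cfg)
        means = patches.data.mean(axis=0)
        centered = patches.data - means
        nonzero = np.linalg.norm(centered, axis=0) > _ZERO_TOL

        self.kmeans_ = None
        self.feature_center_ = None
        self.feature_scale_ = None
        if cfg.n_clusters > 1 and nonzero.any():
            features = _patch_features(patches.data, cfg.patch_size)
            self.feature_center_ = features.mean(axis=0)
            scale = features.std(axis=0)
            self.feature_scale_ = np.where(scale > _ZERO_TOL, scale, 1.0)
            self.kmeans_ = LloydKMeans(
                cfg.n_clusters, n_init=8, random_state=_seed_for(cfg.seed, 0)
            ).fit((features - self.feature_center_) / self.feature_scale_)
            labels = self.kmeans_.labels_
        else:
            labels = np.zeros(patches.n_patches, dtype=int)

        self.dictionaries_ = {}
        self.global_dictionary_ = None
        omp_tol = max(cfg.residual_tol, 1e-9)
        for k in range(cfg.n_clusters):
            member = labels == k
            signals = centered[:, member]
            if not (np.linalg.norm(signals, axis=0) > _ZERO_TOL).any():
                continue  # textureless cluster: zero codes reproduce it
            if member.sum() < cfg.n_atoms:
                logger.warning(
                    "cluster %d has %d patches < %d atoms; falling back to the "
                    "global dictionary",
                    k,
                    int(member.sum()),
                    cfg.n_atoms,
                )
                self._ensure_global(centered, nonzero, cfg, omp_tol)
                continue
            dictionary, _, _ = ksvd_train(
                signals,
                cfg.n_atoms,
                cfg.sparsity,
                n_iter=cfg.ksvd_iters,
                seed=_seed_for(cfg.seed, k + 1),
                residual_tol=omp_tol,
            )
            self.dictionaries_[k] = dictionary
        self._fit_shape_ = pixels.shape
        return self

    def _ensure_global(self, centered, nonzero, cfg, omp_tol) -> None:
        if self.global_dictionary_ is not None:
            return
        if int(nonzero.sum()) < cfg.n_atoms:
            raise ValueError(
                f"image provides {int(nonzero.sum())} textured patches, fewer than "
                f"the {cfg.n_atoms} atoms required for any dictionary"
            )
        dictionary, _, _ = ksvd_train(
            centered,
            cfg.n_atoms,
            cfg.sparsity,
            n_iter=cfg.ksvd_iters,
            seed=_seed_for(cfg.seed, 10_000),
            residual_tol=omp_tol,
        )
        self.global_dictionary_ = dictionary

    # -- coding / reassembly --------------------------------------------

    def transform(self, image) -> np.ndarray:
        cfg = self._config()
        pixels = as_pixels(image)
        patches = extract_patches(pixels, cfg.patch_cfg)
        means = patches.data.mean(axis=0)
        centered = patches.data - means

        if self.kmeans_ is not None:
            features = _patch_features(patches.data, cfg.patch_size)
            scaled = (features - self.feature_center_) / self.feature_scale_
            labels = self.kmeans_.predict(scaled)
        else:
            labels = np.zeros(patches.n_patches, dtype=int)

        recon = np.zeros_like(centered)
        omp_tol = max(cfg.residual_tol, 1e-9)
        for k in range(cfg.n_clusters):
            member = np.flatnonzero(labels == k)
            if member.size == 0:
                continue
            signals = centered[:, member]
            if not (np.linalg.norm(signals, axis=0) > _ZERO_TOL).any():
                continue  # zero codes: flat patches reproduce exactly
            dictionary = self.dictionaries_.get(k, self.global_dictionary_)
            if dictionary is None:
                continue
            codes = omp_encode(dictionary, signals, cfg.sparsity, omp_tol)
            recon[:, member] = dictionary.atoms @ codes.coeffs

        coded = PatchSet(
            data=recon + means,
            origins=patches.origins,
            patch_size=patches.patch_size,
            source_shape=patches.source_shape,
        )
        output = assemble_patches(coded)
        self.label_map_ = _majority_label_map(
            labels, patches, cfg.n_clusters
        )
        return output

    def fit_transform(self, image, y=None) -> np.ndarray:
        return self.fit(image).transform(image)


def _majority_label_map(labels: np.ndarray, patches: PatchSet, n_clusters: int) -> np.ndarray:
    p = patches.patch_size
    h, w = patches.source_shape
    votes = np.zeros((n_clusters, h, w), dtype=np.int32)
    for (r, c), lab in zip(patches.origins, labels):
        votes[lab, r : r + p, c : c + p] += 1
    return np.argmax(votes, axis=0)  # ties -> lowest label


def sdl_denoise(image, cfg: SdlConfig = SdlConfig()):
    """Run the full S-DL denoiser; returns ``(denoised, LabelMap)``."""
    est = SDLDenoiser(
        patch_size=cfg.patch_size,
        stride=cfg.stride,
        n_clusters=cfg.n_clusters,
        n_atoms=cfg.n_atoms,
        sparsity=cfg.sparsity,
        ksvd_iters=cfg.ksvd_iters,
        residual_tol=cfg.residual_tol,
        random_state=cfg.seed,
    )
    output = est.fit_transform(image)
    return output, LabelMap(est.label_map_)


def dl_denoise(image, cfg: SdlConfig = SdlConfig()):
    """Plain dictionary-learning denoiser: S-DL with the clustering stage
    skipped (one global dictionary).  Returns the denoised image."""
    output, _ = sdl_denoise(image, replace(cfg, n_clusters=1))
    return output


def make_central_mask(shape: tuple[int, int], center_fraction: float) -> SamplingMask:
    """Central continuous acquisition: the ``ceil(fraction * height)``
    rows nearest the zero-frequency row (centered layout), all columns;
    symmetric about the center with the extra row on the lower index."""
    if not 0 < center_fraction <= 1:
        raise ValueError("center_fraction must be in (0, 1]")
    h, w = shape
    n_rows = int(np.ceil(center_fraction * h))
    center = h // 2
    start = center - n_rows // 2
    if n_rows % 2 == 0:
        start = center - n_rows // 2  # even count: extra row below center
    rows = np.arange(start, start + n_rows)
    rows = rows[(rows >= 0) & (rows < h)]
    mask = np.zeros((h, w), dtype=bool)
    mask[rows, :] = True
    return SamplingMask(mask, center_fraction=center_fraction)


def sdl_reconstruct(kspace: KSpaceData, cfg: SdlConfig = SdlConfig()):
    """Reconstruct an image from undersampled Fourier data.

    Alternates, for ``cfg.outer_iters`` rounds starting from the
    zero-filled inverse transform: one S-DL denoising pass on the
    current estimate, then the data-consistency replacement
    ``(F(estimate) + nu * measured) / (1 + nu)`` at sampled locations.
    Returns ``(magnitude_image, LabelMap)``.
    """
    mask = kspace.mask.mask
    if not mask.any():
        raise ValueError("sampling mask selects no coefficients")
    if cfg.nu <= 0:
        raise ValueError("reconstruction requires nu > 0")
    measured = np.where(mask, kspace.samples, 0.0 + 0.0j)
    est = np.abs(np.fft.ifft2(np.fft.ifftshift(measured), norm="ortho"))
    label_map = LabelMap(np.zeros(mask.shape, dtype=int))
    for _ in range(cfg.outer_iters):
        denoised, label_map = sdl_denoise(est, cfg)
        coeffs = np.fft.fftshift(np.fft.fft2(denoised.astype(complex), norm="ortho"))
        coeffs[mask] = (coeffs[mask] + cfg.nu * measured[mask]) / (1.0 + cfg.nu)
        est = np.abs(np.fft.ifft2(np.fft.ifftshift(coeffs), norm="ortho"))
    return est, label_map
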