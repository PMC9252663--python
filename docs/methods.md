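# Methods

This note records the models, numerical choices and known limitations of
`segdict` in enough detail to reproduce or contest its results.

## Patch model and pipeline

Images are decomposed into overlapping square patches (side `patch_size` p,
origin stride `stride` ≤ p). Origins follow a regular grid with a final
origin clamped flush to each border whenever `dim − p` is not a multiple of
the stride, so every pixel is covered without padding or synthetic values.
Patches are vectorized row-major; reassembly averages all patch values
covering a pixel (unweighted mean — the standard overlap-average estimator),
which makes extract→assemble an exact inverse for unmodified patches.

The S-DL denoiser: (1) extract patches; (2) cluster them with K-means;
(3) train one K-SVD dictionary per cluster on the mean-subtracted patch
vectors of that cluster; (4) OMP-code every patch against its own cluster's
dictionary and re-add the patch mean; (5) reassemble; (6) emit a label map by
per-pixel majority vote of covering patches' cluster labels (ties to the
lowest label). Plain DL is the same code path with one cluster. Subtracting
the patch mean before coding and restoring it afterwards is the usual way to
keep dictionaries brightness-free.

**Clustering feature.** K-means runs on standardized per-patch texture
descriptors — patch mean, standard deviation, and mean absolute horizontal /
vertical first differences — not on the raw centered patch vectors. Euclidean
distance on raw patch vectors cannot separate shift- or sign-symmetric
textures: two opposite-phase patches of the *same* stripe texture are
farther apart (distance² = 4E) than patches of two orthogonal textures
(distance² = 2E), so a raw-vector K-means actively prefers mixed-orientation
clusters. Measured on two-texture images, raw-vector clustering recovers the
planted partition at chance (~0.5) while the descriptor clustering recovers
it at 0.98–1.0. Descriptor-space clustering for patch grouping is standard
in clustered dictionary-learning practice (e.g. K-LLD). Sparse coding still
operates on the full mean-subtracted patch vectors.

## K-means

Lloyd iterations on squared Euclidean distance: assign each point to its
nearest center (ties to the lowest center index), then move each center to
the mean of its members; the objective H (within-cluster sum of squares) is
recorded each iteration and is non-increasing by construction. Empty
clusters are re-seeded with the point farthest from its assigned center,
stealing only from clusters with more than one member. Initialization is a
seeded draw of K distinct data points (a greedy farthest-first variant is
available), with `n_init` independent restarts keeping the lowest final H —
the pipeline uses 8 restarts. Convergence: relative decrease of H below
`tol` (default 1e-6) or `max_iter` (default 100). All fits are bit-identical
given the seed.

## OMP

Per signal: select the atom with the largest absolute correlation with the
current residual (ties to the lowest atom index), re-solve least squares on
the selected support, stop at `sparsity` atoms or when the residual ℓ2 norm
falls below `residual_tol`. The implementation is batched: selection
maintains an orthonormal basis of each signal's chosen atoms (batched
Gram-Schmidt), and final coefficients come from stacked normal-equation
solves grouped by support size, so no per-signal Python loop runs. An atom
numerically inside the current span (projection residual < 1e-12) is never
added; such signals simply stop growing their support.

Greedy pursuit is *not* globally optimal in general: with coherent
dictionaries it can decisively select a wrong atom. Tests therefore compare
OMP against the exhaustive all-supports least-squares oracle only on
instances satisfying the exact recovery condition
`max_{j∉S} ‖D_S⁺ d_j‖₁ < 1` (the sharp sufficient condition under which
greedy provably finds the planted support) with an additional guard against
near-tied selections.

## K-SVD

Each iteration alternates a full OMP coding pass with sequential atom
updates: for atom j, the residual matrix of the signals using it (with j's
own contribution restored) is approximated by its leading rank-1 SVD term,
replacing the atom (unit-norm left singular vector) and its coefficient row
simultaneously. The SVD sign is fixed so the atom's largest-magnitude entry
is positive, making runs bit-reproducible. The dictionary is initialized
from d distinct nonzero training signals (seeded), normalized. Unused atoms
are replaced by the worst-represented residual direction.

Two safeguards make the per-iteration representation error non-increasing
*by construction* while still escaping the local minima this alternation is
prone to:

* after each coding pass, any column whose fresh OMP code fits worse than
  its previous code keeps the previous one (both are valid codes under the
  current dictionary, so the better one is kept column-wise);
* each iteration first *tentatively* replaces one low-coefficient-energy
  atom with the worst column's residual direction, recodes, and keeps the
  replacement only if the total error strictly decreases — rollback
  otherwise. On noiseless sparse data the worst residual points along
  exactly the structure the dictionary is missing, which is why this escape
  converges: on 500 noiseless signals from a planted minimal-coherence
  16-atom frame, training reaches machine-precision representation error
  within ~20 iterations, where plain K-SVD stalls near 4 % of signal energy.

The planted-recovery experiments use the simplex equiangular tight frame
(16 unit vectors in ℝ^15, pairwise |inner product| = 1/15 — the minimum
possible), randomly rotated per seed, with coefficients of magnitude in
[1, 2]: the regime where greedy coding is provably exact, so the only thing
under test is dictionary learning itself.

## Denoising parameters

`SdlConfig` defaults (library): 8×8 patches, stride 2, K = 4 clusters,
256 atoms per cluster, T₀ = 8, 10 K-SVD iterations, ν = 100 — common K-SVD
denoising practice. The experiment harness uses a lighter configuration
(`desk_config()`: 6×6 patches, stride 2, K = 4, 40 atoms per cluster, T₀ cap
8, 5 K-SVD iterations) so a full five-level × ten-seed sweep of both
algorithms completes in under a minute; the dense stride keeps ~3800 training
patches per image, enough for every cluster's dictionary.

When the corruption level σ is known (as in the sweep, where the noise is
injected), OMP uses noise-matched stopping: `residual_tol = 1.1·σ·p` per
patch, with `sparsity` as a cap. This is the classic K-SVD denoising rule —
fit each patch only down to the noise floor so the coder models signal, not
noise. With a fixed-T₀ rule instead, both S-DL and DL overfit noise at low
levels and the comparison degenerates.

## Undersampled reconstruction

Measurements are modeled as the centered orthonormal 2-D FFT of the image,
kept only on the sampling mask. The central-acquisition mask keeps the
⌈fraction·height⌉ rows nearest the zero-frequency row (extra row on the
lower index for even counts), all columns. Reconstruction starts from the
zero-filled inverse transform and alternates, for `outer_iters` rounds, one
S-DL denoising pass with the data-consistency update
`(F(estimate) + ν·n)/(1+ν)` at sampled locations, returning the magnitude.
Phase is not modeled: denoising operates on the real magnitude estimate and
the transform is applied to it for consistency — a documented
simplification; with ν → ∞ and a full mask the output reduces to the inverse
transform of the data (verified to 1e-6 relative error).

## Phantom

The phantom emulates a B-mode scan of lower-limb edema: four horizontal
bands (skin 8 %, subcutaneous fat 22 %, deep fascia 8 %, muscle the rest;
base echogenicities 0.85 / 0.40 / 0.95 / 0.55), elliptical near-zero
(0.02) lacunae wholly inside the muscle band, and fully developed
multiplicative speckle: per pixel the mean of `speckle_looks` (default 4)
squared magnitudes of unit-variance circular complex Gaussian scatterer
fields, each imaged through a per-layer Gaussian point-spread function and
normalized to unit mean (variance ≈ 1/looks). Per-layer (axial, lateral)
PSF widths — fine skin grain, coarse isotropic fat, laterally smeared
fascia, anisotropic fibrous muscle — give the layers distinct textures, not
just brightnesses, which is both what real tissue looks like and the regime
a segmentation-then-dictionary method is designed for. Pixel-iid speckle
(PSF width 0) is available but makes the clean image white-noise-textured
and hence unrepresentable by any patch-sparse code; denoising gain against
such a reference is structurally impossible at low noise levels, which is
why correlated speckle is the default.

Additive noise follows the stated protocol: zero-mean Gaussian with variance
equal to `variance_fraction × max(image)` (the sweep uses fractions 0.005,
0.01, 0.03, 0.05, 0.10); the complex variant puts independent noise of that
variance on both quadrature channels and returns the magnitude (Rician-type
corruption of the envelope). Reading "% of the maximum" as a fraction of the
maximum intensity (not its square) is a documented interpretation of an
ambiguous convention; the squared reading is available via
``NoiseSpec(..., variance_of_max_squared=True)``.

The two-texture phantom for segmentation-recovery checks plants orthogonal
sinusoidal stripe textures (per-seed frequency and phase jitter, mild
additive noise) on the two halves of the image; recovery is scored as pixel
agreement of the label map with the planted partition up to label
permutation.

What passing phantom tests does and does not show: the generator reproduces
layered anatomy, speckle statistics, anechoic regions and the stated noise
protocol, but not beam-dependent effects (shadowing, attenuation,
refraction), log-compression display curves, or probe geometry; results on
clinical scans may differ accordingly.

## Metrics

The headline error metric is the mean of squared differences (MSE); the
conventional square-rooted RMSE is exposed alongside. PSNR is
`10·log₁₀((2ⁿ−1)²/MSE)` with n the bit depth (n = 1, peak 1, for
unit-intensity phantoms), +∞ for identical images. SSIM is evaluated over
all fully interior windows (default 11×11, uniform weights; Gaussian
weighting by flag) with stabilizers G1 = (0.01·L)², G2 = (0.03·L)²,
L = 2ⁿ−1, and population (ddof 0) window statistics; the implementation is
cross-checked against scikit-image under matching settings.

## Efficacy statistics

Total effective rate = (n − ineffective)/n per group. Group comparison:
Pearson chi-square without continuity correction on the 2×2
effective/ineffective table (df = 1; Yates correction and the full 4×2 test
behind flags) — the uncorrected test matches the common statistical-package
default when all expected counts are ≥ 5, which holds for the packaged
tables (expected counts 22 and 9). Summary-statistics comparisons use the
pooled-variance two-sample t-test. Standard tests are delegated to
scipy.stats; degenerate inputs (zero variances) are handled explicitly.

## Problem sizes in tests and the acceptance script

Unit tests run on small synthetic instances (images ≤ 48², dictionaries
≤ 16×24). The acceptance script uses: the packaged 31+31 outcome tables; 100
qualifying OMP oracle instances (8×16); 500 planted signals for K-SVD (30
iterations); 20 enumerated 10-point clustering trials; the default 128×128
phantom with 5 noise levels × 10 seeds × {input, S-DL, DL}; and 5
two-texture phantoms (96²). The whole script completes in about a minute on
one core.

## Known limitations

* Dictionaries are trained on the noisy image itself (internal learning);
  no cross-image or pretrained dictionaries.
* The reconstruction path ignores phase and coil models; it is a
  single-channel magnitude pipeline.
* The label map is a patch-vote segmentation, not a contour model; its
  granularity is the patch stride.
* K-SVD's objective is non-convex; the rollback-guarded re-seeding escapes
  the common local minima but global convergence is not guaranteed.
* No learned (autoencoder-style) baseline is implemented;
  `compare_algorithms` accepts externally produced images, so three-way
  comparisons with such baselines remain possible.
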