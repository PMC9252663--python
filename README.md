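# segdict

Segmentation dictionary learning (S-DL) for ultrasound image denoising and
undersampled Fourier reconstruction, with the quality metrics and clinical
efficacy statistics needed to evaluate it — aimed at researchers working on
speckle reduction in B-mode imaging (here: lower-limb edema scans) who want a
reproducible, clinical-data-free testbed.

## The method

A grayscale image is decomposed into overlapping p×p patches, vectorized as
columns of a sample matrix M ∈ ℝ^{p²×y}. Patch-based sparse coding models each
patch m as a combination of a few atoms from an overcomplete dictionary
K ∈ ℝ^{x×d} (x = p² < d, unit-norm atoms):

    min ‖α‖₀   s.t.  m = Kα

Exact ℓ0 minimization is intractable; coding uses orthogonal matching pursuit
(OMP: greedily select the atom most correlated with the residual, re-fit by
least squares, stop at T₀ atoms or at a residual tolerance), and dictionary
training uses K-SVD (update each atom and its coefficient row jointly by a
rank-1 SVD of the coding residual restricted to the patches using that atom).

**S-DL** inserts a *segmentation* stage before training: patches are first
clustered by K-means (Lloyd iterations minimizing the within-cluster
sum-of-squares objective H, on standardized per-patch texture descriptors),
and one dictionary is trained *per cluster*, so each tissue texture gets its
own specialized atoms. Plain **DL** is the identical pipeline with one global
dictionary (`n_clusters=1`). The per-pixel majority vote of patch cluster
labels doubles as a segmentation label map.

For undersampled Fourier-domain (k-space) measurements n acquired through a
sampling mask F_u, reconstruction alternates S-DL denoising with a
data-consistency step minimizing

    Σ‖K_pq m − D α_pq‖₂² + ν‖F_u m − n‖₂²,

i.e. at sampled frequencies the coefficient becomes (F(m) + ν·n)/(1 + ν).

Quality is reported as MSE (mean squared difference; the square-rooted
conventional RMSE is also exposed), PSNR = 10·log₁₀((2ⁿ−1)²/MSE) dB, and
mean windowed SSIM. Clinical outcomes (cured / markedly effective /
effective / ineffective per treatment group) are summarized as per-category
and total-effective percentages and compared by Pearson chi-square on the
effective-vs-ineffective dichotomy.

Because no clinical scans ship with the package, a synthetic phantom module
generates layered-tissue B-mode images (skin, subcutaneous fat, fascia,
muscle, with anechoic lacunae in the muscle band and per-layer multi-look
speckle) plus the additive Gaussian noise protocol (variance a stated
fraction of the image maximum, optionally on both quadrature channels).

## Worked example

```python
import numpy as np
from dataclasses import replace
import segdict

clean, truth = segdict.make_phantom(segdict.PhantomSpec(seed=0))
noisy = segdict.add_gaussian_noise(
    clean, segdict.NoiseSpec(0.01, complex_valued=True), seed=7919
)
sigma = float(np.sqrt(0.01 * clean.max()))
cfg = replace(segdict.desk_config(seed=0), residual_tol=1.1 * sigma * 6)
denoised, label_map = segdict.sdl_denoise(noisy, cfg)

print(f"PSNR noisy    {segdict.psnr(clean, noisy, 1):.2f} dB")
print(f"PSNR denoised {segdict.psnr(clean, denoised, 1):.2f} dB")
```

prints (peak = 1 for the unit-intensity phantom)

```
PSNR noisy    15.23 dB
PSNR denoised 17.56 dB
```

a 2.3 dB gain at the 1 % noise level; SSIM rises from 0.805 to 0.855, and
`label_map.labels` segments the tissue bands. The clinical side:

```python
from segdict import OutcomeTable, compare_groups
result = compare_groups(
    OutcomeTable("experimental", 15, 11, 4, 1),
    OutcomeTable("control", 3, 5, 6, 17),
)
print(result.total_effective_pct)   # {'experimental': 96.77..., 'control': 45.16...}
print(result.chi2_statistic)        # 20.04
print(result.p_value)               # 7.6e-06
```

The two outcome tables (31 patients per group) also ship as a packaged CSV
(`segdict.load_outcome_fixture()`).

A `sdl` command-line tool wraps the pipeline: `sdl phantom`, `sdl denoise`,
`sdl dl-denoise`, `sdl reconstruct`, `sdl metrics`, `sdl efficacy`,
`sdl sweep` (run `sdl --help`). Every run writes a JSON provenance record.

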