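# kspacegp

Gaussian-process design of k-space subsampling paths and Bayesian
reconstruction for accelerated 2D MRI.

MRI acquires data in k-space — the 2D spatial-frequency domain — one
trajectory at a time, and scan time is proportional to how much of k-space
is measured. If a library of similar images (for example axial T1-weighted
brain slices) is available, the statistics of their k-space data can stand
in for the unmeasured samples. `kspacegp` implements that idea end to end
for researchers studying undersampled MRI reconstruction:

1. **Library prior.** Every training image is Fourier-transformed, cropped
   to the central `N x N` k-space block, and normalized by the library's
   per-pixel mean magnitude `<|I~|>(k)`, giving order-unity complex fields
   `y(k) = I~(k) / <|I~|>(k)`. The prior is the empirical multivariate
   normal of `y`: per-pixel means `mu0'(k), mu0''(k)` and dense sample
   covariances `K'(k, k'), K''(k, k')` of the real and imaginary channels
   over the flattened grid.
2. **Envelope kernels.** Raw empirical covariances are noisy at long range.
   A symmetric envelope `F(k, k')` is multiplied in elementwise,
   `G = K . F`, with four choices: unity (keep everything), delta (keep only
   the diagonal), a single Gaussian envelope `F_1 = exp(-|k - k'|^2 / L1^2)`
   around the direct point, and a double envelope `F_2 = (a + b)/(1 + ab)`
   (with `a, b` Gaussians around `k' = k` and `k' = -k`) that also keeps the
   Hermitian point — for a real-valued image, `I~(-k) = conj I~(k)`.
3. **Ring-path selection by Bayesian optimization.** Commercial scanners
   can sample concentric circles efficiently, so candidate measurements are
   integer-radius rings. Conditioning the GP on everything sampled so far
   yields posterior means and variances per pixel, combined into the
   intensity-uncertainty acquisition
   `sigma_I(k) = <|I~|> sqrt(mu'^2 s'^2 + mu''^2 s''^2) / sqrt(mu'^2 + mu''^2)`;
   the unsampled ring with the largest angular average of `sigma_I` is
   sampled next, until a pixel budget (e.g. 12.5% of the crop, an eightfold
   acceleration) is reached. Aggregating the per-image paths of a small
   design set by selection frequency gives one generalized open-loop mask.
4. **Reconstruction and scoring.** Unsampled pixels are filled with the GP
   posterior mean, measured pixels keep their values,
   `I~* = [(1 - M)(mu' + i mu'') + M y] <|I~|>`, and the result is
   zero-padded and inverse-transformed. Quality is scored with NMSE
   (`||ref - est||^2 / ||ref||^2`) and SSIM (7x7 uniform window).

A seeded phantom generator produces brain-like 2D cohorts (shared skull
ellipse, randomized interior ellipses, smoothed-noise texture) so the whole
pipeline is testable without downloading any imaging data; axial slices of
real NIfTI volumes can be ingested with the same preparation (resize,
zero-pad to square, max-normalize).

## Worked example

```python
import kspacegp as kg

spec = kg.PhantomSpec(grid_size_full=80)
library = kg.generate_library(130, spec, seed=7, split=(120, 5, 5))

gp = kg.KSpaceGP(crop_size=64, kernel="double").fit(library.subset("stats"))
opt = kg.RingPathOptimizer(gp, budget=0.125).fit(library.subset("path"))
print("generalized ring path:", opt.mask_.radii)
print("sampled fraction of the 64x64 crop: %.4f" % opt.mask_.fraction)

for i, image in enumerate(library.subset("test")):
    res = gp.reconstruct_image(image, opt.mask_)
    print(f"test image {i}: NMSE = {res.nmse:.5f}   SSIM = {res.ssim:.4f}")
```

Output:

```
generalized ring path: [0, 1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14]
sampled fraction of the 64x64 crop: 0.1067
test image 0: NMSE = 0.00444   SSIM = 0.8993
test image 1: NMSE = 0.00536   SSIM = 0.8821
test image 2: NMSE = 0.00249   SSIM = 0.9203
test image 3: NMSE = 0.00428   SSIM = 0.9130
test image 4: NMSE = 0.00361   SSIM = 0.8923
```

The selected mask concentrates on the energy-dense k-space center and
reaches outward with increasing spacing; reconstructing held-out images from
~11% of the crop leaves sub-percent squared error relative to the
crop-limited reference. `KSpaceGP` and `RingPathOptimizer` follow the
scikit-learn estimator conventions (`get_params` / `set_params` /
`fit` / `predict`), and every step is also available as plain functions
(`to_kspace`, `compute_prior_stats`, `apply_envelope`, `posterior`,
`select_path`, `reconstruct`, `nmse`, `ssim`, ...).

A command-line interface mirrors the workflow
(`kspacegp gen-phantoms | build-library | tune | optimize-path |
reconstruct | evaluate | run-all`), driven by a JSON config for `run-all`.

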