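# Methods

## Model

The k-space data of one image is treated as a draw from a multivariate
normal whose moments are estimated from a training library. Images are
Fourier-transformed with the unnormalized forward FFT (inverse carries the
`1/M^2` factor), reordered so the DC coefficient sits at index
`(N/2, N/2)`, and cropped to the central `N x N` block. Because k-space
magnitudes fall off steeply away from DC, all data are normalized pointwise
by the library's mean magnitude `<|I~|>(k)` (the per-pixel mean of
`|I~^p(k)|` over the `n1` training images, floored at `1e-12` times its
grid maximum so division is always defined). Any global constant in this
normalization cancels in reconstruction and leaves the ring ranking
unchanged, which is why the choice of mean versus sum is immaterial; the
mean is used.

The normalized field `y = I~ / <|I~|>` has per-pixel means `mu0'` (real
channel) and `mu0''` (imaginary channel) and dense sample covariances
`K', K''` over the flattened grid (denominator `n1 - 1`, symmetrized
against BLAS round-off). The two channels are modelled independently; no
real/imaginary cross-covariance is estimated.

Envelope kernels shape the covariances elementwise, `G = K . F`:

* `unity` keeps the full empirical covariance;
* `delta` zeroes all off-diagonal entries (reconstruction degenerates to
  the prior-mean fill, a useful baseline);
* `single` keeps a Gaussian neighborhood of the direct point,
  `F_1 = exp(-|k - k'|^2 / L1^2)`;
* `double` additionally keeps the Hermitian point,
  `F_2 = (a + b)/(1 + ab)` with `a = exp(-|k - k'|^2 / L2^2)` and
  `b = exp(-|-k - k'|^2 / L2^2)`, so `F_2 = 1` exactly at `k' = k` and
  `k' = -k` and `0 < F_2 <= 1` everywhere.

`F_1` is a Gaussian (RBF) kernel, hence PSD, and the Schur product
`F_1 . K` of two PSD matrices is PSD. `F_2` is symmetric and bounded but
*not* provably PSD; `kernels.envelope_psd_check` measures its spectrum on a
grid and logs a warning (on a 4x4 grid with `L2 = 2` the most negative
eigenvalue is about `-2e-3` of the largest). The numerical consequences are
handled explicitly (below).

Conditioning on observed pixels `1:m` with values `y_{1:m}` uses the
standard GP posterior per channel:

```
mu(t)      = G(t, 1:m) G(1:m, 1:m)^-1 (y - mu0(1:m)) + mu0(t)
sigma^2(t) = G(t, t)   - G(t, 1:m) G(1:m, 1:m)^-1 G(1:m, t)
```

The acquisition field combines the channels on the unnormalized intensity
scale,

```
sigma_I(k) = <|I~|>(k) sqrt(mu'^2 sigma'^2 + mu''^2 sigma''^2)
             / sqrt(mu'^2 + mu''^2),
```

with `sigma_I = 0` where `mu' = mu'' = 0` (limit convention). The
`mu`-weighting is implemented exactly as defined even though it is not a
standard error-propagation form.

Path selection partitions the grid into integer-radius annuli
(`r = round(|k|)`, half-away-from-zero, `r_max = N/2`; pixels beyond
`r_max` form a corner set that is never sampled and is inferred at
reconstruction). Starting from the unconditioned prior, the unsampled ring
with the largest angular mean of `sigma_I` is "measured" (the image's
normalized values on that ring), the posterior is recomputed from scratch,
and the loop repeats until the next ring would exceed the pixel budget.
Ties break toward the smaller radius (the energy-dense center). Per-image
paths over a design set are aggregated by radius frequency (ties again to
the smaller radius) and rings are added greedily while they fit the budget,
skipping oversized rings — this fixed generalized mask enables open-loop
acquisition. The budget basis is configurable: pixels of the `N x N` crop
(default) or of the full `N0 x N0` image grid.

Reconstruction fills unsampled pixels with the posterior mean and keeps
measurements where known, `I~* = [(1 - M)(mu' + i mu'') + M y] <|I~|>`,
then zero-pads to `N0 x N0` and inverse-transforms (magnitude). Data
consistency at sampled pixels is exact by construction.

## Numerical choices

* **Observed-block solve.** `G(1:m, 1:m)` is factorized by Cholesky with an
  adaptive diagonal jitter ladder: a plain attempt first, then
  `1e-10 ... 1e-4` times the mean diagonal, escalating tenfold. Empirical
  covariances have rank at most `n1 - 1`, so jitter is routinely needed
  once `m` exceeds the library size.
* **Indefinite blocks.** Because `F_2 . K` can be indefinite, the ladder
  may fail outright, or succeed barely and amplify noise directions. In
  either case the solver falls back to a truncated-eigendecomposition
  pseudo-inverse keeping directions above
  `max(1e-5 * lambda_max, 10 * |lambda_min^-|)`; weaker directions couple
  to the indefiniteness of the full shaped covariance and blow up when
  inverted. The regularization strength actually used is reported as
  `jitter_used`.
* **Negative posterior variances.** Values within `-1e-9` of zero (times
  the prior-diagonal scale) are round-off and clipped silently; values down
  to `-0.05` of scale are clipped with a log record — they are genuine
  consequences of the double envelope's indefiniteness, not bugs (measured
  magnitudes reach a few `1e-3` at realistic sizes); anything larger raises,
  as only an implementation error produces order-one negatives.
* **Variance-monotonicity caveat.** Posterior-variance contraction as
  observations accumulate is a theorem only for PSD covariances; it holds
  to round-off for `unity`/`single` and is violated at the `1e-2` level by
  `double`. Tests assert it for the PSD single envelope.
* **Ties and determinism.** All argmax/argmin steps break ties
  deterministically (smaller radius, smaller length-scale candidate), and
  every random quantity derives from one root seed via
  `SeedSequence((root, index))` child seeds, so library membership is
  stable when a library grows and whole runs are bit-reproducible.

## Hyperparameters

| parameter | meaning | default |
| --- | --- | --- |
| `crop_size N` | retained central k-space block (pixels) | 64 |
| `kernel` | envelope kind | `double` |
| `length_scale L` | envelope width in k-space pixels | `round(0.09 N)` |
| `budget` | sampled fraction of the budget basis | 0.125 |
| `budget_basis` | crop (`N^2`) or full (`N0^2`) pixels | crop |
| `eps_scale` | relative floor on the mean magnitude | 1e-12 |

The `0.09 N` default reflects that useful envelope widths scale with the
grid; tuning on held-out images is provided (`tune_length_scale` minimizes
mean reconstruction NMSE over a candidate list through a fixed mask, ties
to the smaller candidate — preferring the sparser covariance). Envelope
widths shrink with smaller training libraries, so per-library tuning is
recommended; the tuning subset is a parameter (default: the path-design
subset).

## Synthetic cohorts

`phantoms` generates seeded 2D cohorts standing in for a library of brain
slices: a deterministic outer "skull" ellipse at a background intensity
(0.5), `n_ellipses = 8` interior ellipses with seeded centers, axes,
orientations and intensities in [0.2, 0.95], plus smoothed-noise texture
(white noise convolved with an isotropic Gaussian, correlation length 3 px,
amplitude 0.08) masked to the skull, max-normalized to [0, 1]. Default
grids are 64-80 px (tests use 40-80) so the `N^2 x N^2` covariances stay
desk-sized; the covariance-convergence check uses a 32-px crop because it
varies `n1` over 100-3200, not the grid. These choices emulate a cohort
sharing anatomy-scale spatial correlations — which is what makes the
empirical covariance informative — and were fixed before any acceptance
measurements.

What the cohort does *not* emulate: MR acquisition physics (coil
sensitivities, noise spectra, relaxation contrast), inter-subject anatomy
beyond random interior ellipses, and scanner phase errors (all images are
exactly real, so k-space is exactly Hermitian). The last point matters for
interpreting kernel comparisons: with exactly real images and rings closed
under `k -> -k`, the covariance columns at `k` and `-k` are numerically
identical, so the double envelope's Hermitian peak duplicates information
the single envelope already uses, and the two perform within ~1% of each
other at an eightfold acceleration (the double envelope leads at stronger
accelerations, e.g. 2.5% sampling). Passing tests on this cohort therefore
demonstrate the machinery and the qualitative trends (budget monotonicity,
envelope-vs-raw-covariance ordering), not the full-scale margins between
the two envelope kernels reported on real multi-subject libraries.

## Problem sizes

The bundled study (`experiments.kernel_comparison_study`, also driven by
`scripts/acceptance.py`) uses `N0 = 80`, `N = 64` and a 400/20/40 split —
sizes chosen so dense `4096^2` covariances and the full four-kernel
comparison run comfortably on a single CPU. Full-scale runs (e.g.
`N = 160`, thousands of training images) are configurable but memory- and
time-hungry: the dense covariance pair alone at `N = 160` occupies ~10 GB.

## Known limitations

* Dense covariance storage; no streaming or low-rank estimation.
* Ring-shaped trajectories only (no Cartesian lines, radial lines or
  spirals) and no closed-loop scanner integration.
* The double envelope is applied exactly as defined; making it PSD (e.g.
  by spectral clipping of `F_2` itself) is deliberately out of scope.
* Metrics are computed on the zero-padded magnitude image against the
  crop-limited reference by default (so full sampling scores perfectly);
  scoring against the uncropped original is available via the functional
  API by passing that image as `reference`.
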