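"""Scikit-learn-style estimators tying the pipeline together.

``KSpaceGP`` is the fitted library prior plus envelope covariance: ``fit``
on a stack of real images learns the k-space mean magnitude, channel means
and covariances and shapes them with the chosen envelope kernel; ``predict``
reconstructs images observed through a sampling mask, and ``score`` returns
the negative mean NMSE (higher is better, sklearn convention).

``RingPathOptimizer`` is a meta-estimator over a fitted ``KSpaceGP``: its
``fit`` runs the Bayesian-optimization ring selection for each supplied
image and aggregates the traces into the generalized open-loop mask
(``mask_``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .kernels import EnvelopeKernel, apply_envelope, default_length_scale
from .kspace import to_kspace
from .posterior import ObservationSet, intensity_uncertainty, posterior
from .reconstruct import ReconstructionResult, crop_limited_reference, reconstruct, subsample
from .rings import SamplingMask, generalized_path, ring_partition, select_path
from .stats import EPS_SCALE, compute_prior_stats

__all__ = ["KSpaceGP", "RingPathOptimizer"]


def _check_image_stack(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError("X must be an (n_images, N0, N0) stack of square images")
    if X.shape[1] % 2:
        raise ValueError("image size must be even")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


class KSpaceGP(BaseEstimator):
    """Gaussian-process prior over centered k-space, with envelope covariance.

    Parameters
    ----------
    crop_size : even side length of the central k-space block kept for the
        model (``None`` keeps the full grid).
    kernel : envelope kind, one of ``unity | delta | single | double``.
    length_scale : envelope length scale in k-space pixels; ``None`` uses the
        grid-relative default ``round(0.09 N)`` for single/double.
    eps_scale : relative floor on the mean magnitude.
    materialize : precompute the full shaped covariance matrices.

    Attributes (after ``fit``)
    ----------
    stats_ : LibraryStats with ``mean_magnitude``, ``mu0_re/im``, ``K_re/im``.
    kernel_ : resolved EnvelopeKernel.
    cov_ : ModifiedCovariance (the shaped ``G'``/``G''``).
    source_size_ : training image side length ``N0`` (default padding target).
    """

    def __init__(
        self,
        crop_size: int | None = 64,
        kernel: str = "double",
        length_scale: float | None = None,
        eps_scale: float = EPS_SCALE,
        materialize: bool = True,
    ):
        self.crop_size = crop_size
        self.kernel = kernel
        self.length_scale = length_scale
        self.eps_scale = eps_scale
        self.materialize = materialize

    def fit(self, X, y=None):
        X = _check_image_stack(X)
        crop = X.shape[1] if self.crop_size is None else int(self.crop_size)
        kdata = [to_kspace(img, crop) for img in X]
        self.stats_ = compute_prior_stats(kdata, eps_scale=self.eps_scale)
        ls = self.length_scale
        if ls is None and self.kernel in ("single", "double"):
            ls = default_length_scale(crop)
        self.kernel_ = EnvelopeKernel(self.kernel, ls)
        self.cov_ = apply_envelope(self.stats_, self.kernel_, materialize=self.materialize)
        self.source_size_ = X.shape[1]
        self.n_images_ = X.shape[0]
        return self

    def fit_from_stats(self, stats, source_size: int | None = None):
        """Fit from precomputed :class:`LibraryStats` (the prior is
        kernel-independent, so several kernels can share one estimate)."""
        self.stats_ = stats
        ls = self.length_scale
        if ls is None and self.kernel in ("single", "double"):
            ls = default_length_scale(stats.N)
        self.kernel_ = EnvelopeKernel(self.kernel, ls)
        self.cov_ = apply_envelope(self.stats_, self.kernel_, materialize=self.materialize)
        self.source_size_ = stats.N if source_size is None else int(source_size)
        self.n_images_ = stats.n1
        return self

    def _require_fitted(self):
        if not hasattr(self, "stats_"):
            raise NotFittedError("KSpaceGP must be fitted before use")

    # -- inference -------------------------------------------------------

    def posterior(self, obs: ObservationSet, want_variance: bool = True):
        self._require_fitted()
        return posterior(self.cov_, self.stats_, obs, want_variance=want_variance)

    def uncertainty(self, obs: ObservationSet):
        """Acquisition field ``sigma_I`` given current observations."""
        self._require_fitted()
        return intensity_uncertainty(self.posterior(obs), self.stats_.mean_magnitude)

    def reconstruct_image(
        self, image: np.ndarray, mask: SamplingMask, pad_to: int | None = None
    ) -> ReconstructionResult:
        """Subsample one ground-truth image through ``mask`` and reconstruct it,
        scored against its crop-limited reference."""
        self._require_fitted()
        pad = self.source_size_ if pad_to is None else int(pad_to)
        k = to_kspace(np.asarray(image, float), self.stats_.N)
        obs = subsample(k, mask, self.stats_.mean_magnitude)
        ref = crop_limited_reference(k, pad_to=pad)
        return reconstruct(obs, mask, self.stats_, self.cov_, pad_to=pad, reference=ref)

    def predict(self, X, mask: SamplingMask, pad_to: int | None = None) -> np.ndarray:
        """Reconstructed images for a stack observed through ``mask``."""
        X = _check_image_stack(X)
        return np.stack([self.reconstruct_image(img, mask, pad_to).image_star for img in X])

    def score(self, X, y=None, mask: SamplingMask | None = None) -> float:
        """Negative mean NMSE over ``X`` (higher is better)."""
        if mask is None:
            raise ValueError("score requires a sampling mask")
        X = _check_image_stack(X)
        errs = [self.reconstruct_image(img, mask).nmse for img in X]
        return -float(np.mean(errs))


class RingPathOptimizer(BaseEstimator):
    """Selects the generalized ring sampling mask from per-image BO paths.

    Parameters
    ----------
    gp : a fitted ``KSpaceGP`` supplying the prior and covariance.
    budget : maximal sampled fraction of k-space.
    budget_basis : ``"crop"`` (N x N pixels, default) or ``"full"``
        (N0 x N0 pixels of the uncropped image grid).

    Attributes (after ``fit``)
    ----------
    partition_ : RingPartition of the crop grid.
    traces_ : list of PathTrace, one per training image.
    mask_ : generalized SamplingMask.
    """

    def __init__(self, gp: KSpaceGP = None, budget: float = 0.125, budget_basis: str = "crop"):
        self.gp = gp
        self.budget = budget
        self.budget_basis = budget_basis

    def fit(self, X, y=None):
        if self.gp is None:
            raise ValueError("RingPathOptimizer requires a fitted KSpaceGP")
        self.gp._require_fitted()
        X = _check_image_stack(X)
        stats = self.gp.stats_
        part = ring_partition(stats.N)
        basis = part.basis(self.budget_basis, full_size=self.gp.source_size_)
        traces = []
        for img in X:
            k = to_kspace(img, stats.N)
            traces.append(select_path(k, stats, self.gp.cov_, part, self.budget, basis))
        self.partition_ = part
        self.basis_ = basis
        self.traces_ = traces
        self.mask_ = generalized_path(traces, part, self.budget, basis)
        return self

    def transform(self, X) -> np.ndarray:
        """Reconstruct a stack of images through the fitted mask."""
        if not hasattr(self, "mask_"):
            raise NotFittedError("RingPathOptimizer must be fitted before transform")
        return self.gp.predict(X, self.mask_)
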