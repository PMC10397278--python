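"""Empirical k-space statistics of an image library.

The library prior of the Gaussian process is a pair of per-pixel means and a
pair of dense covariance matrices, estimated from the normalized k-space data
of a training library:

* ``mean_magnitude`` — per-pixel mean of ``|I~^p(k)|`` over the library,
  used to normalize all k-space data to order unity;
* ``y^p(k) = I~^p(k) / mean_magnitude(k)`` — the normalized complex field;
* ``mu0' , mu0''`` — per-pixel means of ``Re[y]`` and ``Im[y]``;
* ``K' , K''`` — sample covariances (denominator ``n1 - 1``) of ``Re[y]``
  and ``Im[y]`` over the flattened grid, each ``N^2 x N^2``.

Real and imaginary channels are modelled independently; no cross-covariance
is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kspace import Grid, KSpaceData

__all__ = [
    "LibraryStats",
    "compute_mean_magnitude",
    "normalize",
    "compute_prior_stats",
]

#: relative floor applied to the mean magnitude (times its grid maximum)
EPS_SCALE = 1e-12


def _as_stack(library) -> np.ndarray:
    """Stack a collection of KSpaceData (or arrays) into ``(n, N, N)`` complex."""
    items = list(library)
    if len(items) == 0:
        raise ValueError("library must be non-empty")
    arrs = []
    for it in items:
        vals = it.values if isinstance(it, KSpaceData) else np.asarray(it, dtype=complex)
        arrs.append(vals)
    stack = np.stack(arrs)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("library members must share a square N x N grid")
    if not np.all(np.isfinite(stack.view(float))):
        raise ValueError("library contains non-finite k-space values")
    return stack


@dataclass
class LibraryStats:
    """Empirical prior of the normalized k-space field over a flattened grid."""

    mean_magnitude: np.ndarray  # (N, N), > 0 everywhere
    mu0_re: np.ndarray  # (N^2,)
    mu0_im: np.ndarray  # (N^2,)
    K_re: np.ndarray  # (N^2, N^2), symmetric
    K_im: np.ndarray  # (N^2, N^2), symmetric
    n1: int
    eps: float = 0.0

    def __post_init__(self):
        N = self.mean_magnitude.shape[0]
        if self.mean_magnitude.shape != (N, N):
            raise ValueError("mean_magnitude must be square")
        n2 = N * N
        for name in ("mu0_re", "mu0_im"):
            if getattr(self, name).shape != (n2,):
                raise ValueError(f"{name} must have shape ({n2},)")
        for name in ("K_re", "K_im"):
            if getattr(self, name).shape != (n2, n2):
                raise ValueError(f"{name} must have shape ({n2}, {n2})")
        if np.any(self.mean_magnitude <= 0):
            raise ValueError("mean_magnitude must be strictly positive")

    @property
    def N(self) -> int:
        return self.mean_magnitude.shape[0]

    @property
    def grid(self) -> Grid:
        return Grid(self.N)


def compute_mean_magnitude(library, eps_scale: float = EPS_SCALE) -> np.ndarray:
    """Per-pixel mean of ``|I~^p(k)|`` over the library, floored at
    ``eps_scale`` times the grid maximum so later division is safe."""
    stack = _as_stack(library)
    mm = np.abs(stack).mean(axis=0)
    top = mm.max()
    if top <= 0:
        raise ValueError("library mean magnitude is identically zero")
    return np.maximum(mm, eps_scale * top)


def normalize(k: KSpaceData, mean_magnitude: np.ndarray) -> np.ndarray:
    """Normalized complex field ``y(k) = I~(k) / <|I~|>(k)`` (pointwise)."""
    mm = np.asarray(mean_magnitude, dtype=float)
    if mm.shape != k.values.shape:
        raise ValueError("mean_magnitude shape does not match k-space data")
    if np.any(mm <= 0):
        raise ValueError("mean_magnitude must be strictly positive")
    return k.values / mm


def compute_prior_stats(library, eps_scale: float = EPS_SCALE) -> LibraryStats:
    """Estimate the library prior (means and covariances of the normalized field).

    Requires ``n1 >= 2`` members (sample covariances use an ``n1 - 1``
    denominator). Matrices are explicitly symmetrized against BLAS round-off.
    """
    stack = _as_stack(library)
    n1 = stack.shape[0]
    if n1 < 2:
        raise ValueError(f"need at least 2 library members for covariances, got {n1}")
    mm = compute_mean_magnitude(stack, eps_scale=eps_scale)
    y = stack / mm  # (n1, N, N)
    n2 = mm.size
    yr = y.real.reshape(n1, n2)
    yi = y.imag.reshape(n1, n2)
    mu0_re = yr.mean(axis=0)
    mu0_im = yi.mean(axis=0)
    cr = yr - mu0_re
    ci = yi - mu0_im
    K_re = cr.T @ cr / (n1 - 1)
    K_im = ci.T @ ci / (n1 - 1)
    K_re = (K_re + K_re.T) / 2.0
    K_im = (K_im + K_im.T) / 2.0
    eps = eps_scale * np.abs(stack).mean(axis=0).max()
    return LibraryStats(
        mean_magnitude=mm,
        mu0_re=mu0_re,
        mu0_im=mu0_im,
        K_re=K_re,
        K_im=K_im,
        n1=n1,
        eps=float(eps),
    )
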