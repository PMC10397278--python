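"""Reconstruction of subsampled k-space and NMSE/SSIM scoring.

Reconstruction fills the unsampled pixels with the Gaussian-process posterior
mean of the normalized field and keeps the measured values where known:

    I~*(k) = [ (1 - M(k)) (mu'(k) + i mu''(k)) + M(k) y(k) ] <|I~|>(k)

The reconstructed k-space block is zero-padded to the target image size and
inverted (magnitude taken). By default, quality is measured against the
crop-limited reference — the ground-truth k-space cropped to the same block,
padded and inverted — so a fully sampled mask scores perfectly and crop loss
is not charged to the inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .kernels import ModifiedCovariance
from .kspace import KSpaceData, from_kspace
from .posterior import ObservationSet, posterior
from .rings import SamplingMask
from .stats import LibraryStats, normalize

__all__ = [
    "ReconstructionResult",
    "subsample",
    "reconstruct",
    "crop_limited_reference",
    "nmse",
    "ssim",
]

SSIM_WIN = 7  # uniform sliding window; stability constants K1=0.01, K2=0.03


@dataclass
class ReconstructionResult:
    k_star: np.ndarray  # complex (N, N)
    image_star: np.ndarray  # real (pad_to, pad_to)
    nmse: float | None
    ssim: float | None
    mask_fraction: float
    jitter_used: float = 0.0


def subsample(k: KSpaceData, mask: SamplingMask, mean_magnitude: np.ndarray) -> ObservationSet:
    """Observations of the normalized field ``y`` at the mask's nonzero pixels."""
    if mask.mask.shape != k.values.shape:
        raise ValueError("mask shape does not match k-space data")
    idx = np.flatnonzero(mask.mask.ravel())
    y = normalize(k, mean_magnitude).ravel()
    return ObservationSet(indices=idx, values=y[idx])


def crop_limited_reference(k: KSpaceData, pad_to: int | None = None) -> np.ndarray:
    """Ground-truth image seen through the same central k-space crop."""
    return from_kspace(k, pad_to=pad_to)


def reconstruct(
    obs: ObservationSet,
    mask: SamplingMask,
    stats: LibraryStats,
    cov: ModifiedCovariance,
    pad_to: int | None = None,
    reference: np.ndarray | None = None,
) -> ReconstructionResult:
    """GP reconstruction of subsampled k-space, padded inversion and scoring.

    ``obs`` must cover exactly the mask's nonzero pixels. When a ``reference``
    image is supplied, NMSE and SSIM are filled in.
    """
    N = stats.N
    if mask.mask.shape != (N, N):
        raise ValueError("mask shape does not match library stats")
    m_flat = mask.mask.ravel().astype(bool)
    mask_idx = np.flatnonzero(m_flat)
    order = np.argsort(obs.indices)
    if not np.array_equal(obs.indices[order], mask_idx):
        raise ValueError("observation indices do not match the mask's nonzero pixels")
    y_full = np.zeros(N * N, dtype=complex)
    y_full[obs.indices] = obs.values

    jitter = 0.0
    n_unobs = N * N - mask_idx.size
    if n_unobs > 0:
        fld = posterior(cov, stats, obs, want_variance=False)
        mu = (fld.mu_re + 1j * fld.mu_im).ravel()
        jitter = fld.jitter_used
    else:  # fully sampled: no inference needed
        mu = np.zeros(N * N, dtype=complex)

    mm_flat = stats.mean_magnitude.ravel()
    k_star_flat = np.where(m_flat, y_full, mu) * mm_flat
    k_star = k_star_flat.reshape(N, N)
    pad = int(pad_to) if pad_to is not None else N
    image_star = from_kspace(KSpaceData(k_star, source_size=pad), pad_to=pad)

    err = sim = None
    if reference is not None:
        err = nmse(reference, image_star)
        sim = ssim(reference, image_star)
    return ReconstructionResult(
        k_star=k_star,
        image_star=image_star,
        nmse=err,
        ssim=sim,
        mask_fraction=mask_idx.size / m_flat.size,
        jitter_used=jitter,
    )


def nmse(reference: np.ndarray, estimate: np.ndarray) -> float:
    """``||ref - est||_F^2 / ||ref||_F^2``."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("reference and estimate must share a shape")
    denom = float(np.sum(ref * ref))
    if denom == 0.0:
        raise ValueError("reference image is identically zero")
    return float(np.sum((ref - est) ** 2)) / denom


def ssim(reference: np.ndarray, estimate: np.ndarray) -> float:
    """Mean structural similarity with a 7x7 uniform window.

    Stability constants ``C1 = (0.01 R)^2`` and ``C2 = (0.03 R)^2`` with
    ``R`` the reference maximum.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("reference and estimate must share a shape")
    if min(ref.shape) < SSIM_WIN:
        raise ValueError(f"image smaller than the {SSIM_WIN}x{SSIM_WIN} SSIM window")
    data_range = float(ref.max())
    if data_range <= 0:
        raise ValueError("reference image must have a positive maximum")
    return float(
        structural_similarity(
            ref, est, win_size=SSIM_WIN, gaussian_weights=False, data_range=data_range
        )
    )
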