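"""Seeded brain-like phantom cohorts.

Each phantom is a 2D piecewise-elliptical image on an even square grid: a
fixed outer "skull" ellipse at a background intensity, a seeded number of
interior ellipses with random centers, axes, orientations and intensities,
and a smoothed-noise texture (white noise convolved with an isotropic
Gaussian) that gives the k-space spectrum a natural-image-like decay. The
final image is max-normalized to [0, 1].

A cohort shares the skull geometry and the statistical recipe for its
interior structure, so the empirical k-space covariance of a library of
phantoms carries anatomy-scale correlations worth learning — the property
the real training cohorts of T1-weighted brain slices provide. The generator
makes no attempt at MR physics (no coil sensitivities, noise spectra or
relaxation contrast).

Reproducibility: one root seed; image ``i`` uses the child seed derived from
``SeedSequence((root, i))``, so library membership is stable when the library
grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "PhantomLibrary",
    "generate_phantom",
    "generate_library",
    "add_lesion",
    "child_seed",
]

# skull semi-axes as a fraction of the grid (seed-independent)
_SKULL_A = 0.46
_SKULL_B = 0.38
_PARTITION_SALT = 0x9E3779B9


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom cohort."""

    grid_size_full: int = 64
    n_ellipses: int = 8
    intensity_range: tuple = (0.2, 0.95)
    texture_strength: float = 0.08
    texture_corr_len: float = 3.0
    background: float = 0.5
    lesion: tuple | None = None  # (center, radii, contrast)

    def validate(self) -> None:
        if self.grid_size_full <= 0 or self.grid_size_full % 2:
            raise ValueError("grid_size_full must be a positive even integer")
        if self.n_ellipses < 0:
            raise ValueError("n_ellipses must be >= 0")
        lo, hi = self.intensity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("intensity_range must satisfy 0 <= lo <= hi <= 1")
        if self.texture_strength < 0:
            raise ValueError("texture_strength must be >= 0")
        if self.texture_corr_len <= 0:
            raise ValueError("texture_corr_len must be > 0")
        if not 0 <= self.background <= 1:
            raise ValueError("background must lie in [0, 1]")


def _ellipse_mask(N: int, center, radii, angle: float = 0.0) -> np.ndarray:
    """Boolean mask of a (rotated) ellipse; parts beyond the grid are clipped."""
    cy, cx = center
    ry, rx = radii
    if ry <= 0 or rx <= 0:
        raise ValueError("ellipse radii must be positive")
    yy, xx = np.mgrid[0:N, 0:N]
    y = yy - (N - 1) / 2.0 - cy
    x = xx - (N - 1) / 2.0 - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * y + sa * x
    v = -sa * y + ca * x
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int) -> np.ndarray:
    """One phantom image; deterministic for fixed ``(spec, seed)``."""
    spec.validate()
    rng = np.random.default_rng(seed)
    N = spec.grid_size_full
    skull = _ellipse_mask(N, (0.0, 0.0), (_SKULL_B * N, _SKULL_A * N))
    img = spec.background * skull.astype(float)
    lo, hi = spec.intensity_range
    for _ in range(spec.n_ellipses):
        center = rng.uniform(-0.26, 0.26, size=2) * N
        radii = rng.uniform(0.04, 0.17, size=2) * N
        angle = rng.uniform(0.0, np.pi)
        value = rng.uniform(lo, hi)
        img[_ellipse_mask(N, center, radii, angle) & skull] = value
    if spec.texture_strength > 0:
        noise = rng.standard_normal((N, N))
        tex = gaussian_filter(noise, spec.texture_corr_len)
        img += spec.texture_strength * tex * skull
    if spec.lesion is not None:
        img = add_lesion(img, spec.lesion, normalize=False)
    np.clip(img, 0.0, None, out=img)
    top = img.max()
    if top > 0:
        img /= top
    return img


def add_lesion(image: np.ndarray, lesion, normalize: bool = True) -> np.ndarray:
    """Multiply an elliptical region's intensity by ``(1 + contrast)``.

    The rest of the image is untouched; results are clipped to [0, 1]
    (skipped when ``normalize=False``, for use mid-generation).
    """
    center, radii, contrast = lesion
    if contrast < -1:
        raise ValueError("lesion contrast must be >= -1")
    img = np.asarray(image, dtype=float).copy()
    N = img.shape[0]
    cy, cx = center
    ry, rx = radii
    half = (N - 1) / 2.0
    if abs(cy) + ry > half + 0.5 or abs(cx) + rx > half + 0.5:
        raise ValueError("lesion must lie inside the grid")
    mask = _ellipse_mask(N, center, radii)
    img[mask] *= 1.0 + contrast
    if normalize:
        np.clip(img, 0.0, 1.0, out=img)
    return img


def child_seed(root_seed: int, index: int) -> int:
    """Stable per-image seed (< 2**31) derived from the root seed."""
    state = np.random.SeedSequence((int(root_seed), int(index))).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


@dataclass
class PhantomLibrary:
    """A generated cohort with its three-way partition."""

    images: np.ndarray  # (n, N0, N0)
    partitions: dict  # 'stats' / 'path' / 'test' -> sorted index arrays
    seed: int
    spec: PhantomSpec

    @property
    def n(self) -> int:
        return self.images.shape[0]

    def subset(self, name: str) -> np.ndarray:
        return self.images[self.partitions[name]]


def generate_library(n: int, spec: PhantomSpec, seed: int, split) -> PhantomLibrary:
    """``n`` phantoms from child seeds, partitioned into disjoint
    stats/path/test subsets of sizes ``split = (n1, n2, n3)``."""
    n1, n2, n3 = (int(s) for s in split)
    if min(n1, n2, n3) < 0 or n1 + n2 + n3 != n:
        raise ValueError(f"split {split} does not sum to n={n}")
    images = np.stack([generate_phantom(spec, child_seed(seed, i)) for i in range(n)])
    perm_rng = np.random.default_rng(np.random.SeedSequence((int(seed), _PARTITION_SALT)))
    perm = perm_rng.permutation(n)
    partitions = {
        "stats": np.sort(perm[:n1]),
        "path": np.sort(perm[n1 : n1 + n2]),
        "test": np.sort(perm[n1 + n2 :]),
    }
    return PhantomLibrary(images=images, partitions=partitions, seed=int(seed), spec=spec)
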