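"""Centered 2D k-space transforms and grid conventions.

A real-space image ``I(x)`` on an even ``N0 x N0`` grid maps to a complex
k-space grid ``I~(k)`` via an unnormalized forward FFT, reordered so the
zero-frequency (DC) coefficient sits at index ``(c, c)`` with ``c = N // 2``.
The inverse direction embeds the (possibly cropped) k-space block centrally
in a larger zero grid, applies the ``1/M^2``-normalized inverse FFT and takes
the magnitude.

Transform convention (fixed throughout the package):

* forward: ``numpy.fft.fft2`` (no scaling), then ``fftshift``;
* inverse: ``ifftshift`` then ``numpy.fft.ifft2`` (scaling ``1/M^2`` where
  ``M`` is the padded grid size).

With this pair, Parseval's identity reads
``sum |I|^2 = sum |I~|^2 / N0^2`` for an uncropped transform.

Flattening is row-major: pixel ``(i, j)`` has flat index ``t = i*N + j`` and
k-coordinate ``k(i, j) = (i - c, j - c)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "KSpaceData", "to_kspace", "from_kspace"]


class Grid:
    """Row-major flattening and k-coordinates of an even ``N x N`` grid.

    The DC pixel is ``(c, c)`` with ``c = N // 2``; pixel ``(i, j)`` carries the
    integer frequency coordinate ``k = (i - c, j - c)``.
    """

    def __init__(self, N: int):
        N = int(N)
        if N <= 0 or N % 2:
            raise ValueError(f"grid size must be a positive even integer, got {N}")
        self.N = N
        self.c = N // 2

    def coords(self) -> np.ndarray:
        """All k-coordinates as an ``(N^2, 2)`` float array in flat order."""
        idx = np.arange(self.N) - self.c
        ki, kj = np.meshgrid(idx, idx, indexing="ij")
        return np.stack([ki.ravel(), kj.ravel()], axis=1).astype(float)

    def flat_index(self, i, j):
        return np.asarray(i) * self.N + np.asarray(j)

    def radius(self) -> np.ndarray:
        """``|k|`` for every pixel, flat order."""
        xy = self.coords()
        return np.hypot(xy[:, 0], xy[:, 1])


@dataclass
class KSpaceData:
    """A centered complex k-space grid.

    Attributes
    ----------
    values : complex ``(N, N)`` array with DC at ``(N//2, N//2)``.
    source_size : side length ``N0`` of the real-space image the data came
        from (used as the default zero-padding target on inversion).
    """

    values: np.ndarray
    source_size: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("k-space values must be a square 2D array")
        if self.values.shape[0] % 2:
            raise ValueError("k-space grid size must be even")
        if self.values.shape[0] > self.source_size:
            raise ValueError("k-space grid cannot exceed its source image size")
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("k-space values must be finite")

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def grid(self) -> Grid:
        return Grid(self.N)


def to_kspace(image: np.ndarray, crop_N: int | None = None) -> KSpaceData:
    """Forward FFT of a real image with the central ``crop_N x crop_N`` block kept.

    Parameters
    ----------
    image : real ``N0 x N0`` array, ``N0`` even.
    crop_N : even crop size ``<= N0``; ``None`` keeps the full grid.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be a square 2D array")
    N0 = img.shape[0]
    if N0 % 2:
        raise ValueError("image size must be even")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if crop_N is None:
        crop_N = N0
    crop_N = int(crop_N)
    if crop_N % 2:
        raise ValueError("crop size must be even (Hermitian indexing assumes even N)")
    if not 0 < crop_N <= N0:
        raise ValueError(f"crop size {crop_N} outside (0, {N0}]")
    k = np.fft.fftshift(np.fft.fft2(img))
    c0, h = N0 // 2, crop_N // 2
    vals = k[c0 - h : c0 + h, c0 - h : c0 + h].copy()
    return KSpaceData(vals, source_size=N0)


def from_kspace(k: KSpaceData, pad_to: int | None = None) -> np.ndarray:
    """Magnitude image from (zero-padded) centered k-space.

    The ``N x N`` block is embedded centrally in a ``pad_to x pad_to`` zero
    grid (default ``k.source_size``) before the normalized inverse FFT.
    """
    if pad_to is None:
        pad_to = k.source_size
    pad_to = int(pad_to)
    if pad_to < k.N:
        raise ValueError(f"pad_to={pad_to} smaller than k-space size {k.N}")
    if pad_to % 2:
        raise ValueError("pad_to must be even")
    full = np.zeros((pad_to, pad_to), dtype=complex)
    c, h = pad_to // 2, k.N // 2
    full[c - h : c + h, c - h : c + h] = k.values
    img = np.fft.ifft2(np.fft.ifftshift(full))
    return np.abs(img)
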