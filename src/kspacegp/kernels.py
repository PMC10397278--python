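"""Envelope kernels that shape the empirical k-space covariances.

An empirical covariance learned from a finite library carries noise in its
long-range entries. The remedy is a symmetric positive function
``F(k, k')`` multiplied elementwise into ``K'`` and ``K''``:

* ``unity`` — ``F = 1``: keep the full empirical covariance;
* ``delta`` — ``F = 1`` iff ``k = k'``: discard all off-diagonal structure
  (reconstruction falls back to the prior mean);
* ``single`` — ``F_1 = exp(-|k - k'|^2 / L1^2)``: a Gaussian envelope around
  the direct point ``k' = k``;
* ``double`` — ``F_2 = (a + b) / (1 + a b)`` with
  ``a = exp(-|k - k'|^2 / L2^2)`` and ``b = exp(-|-k - k'|^2 / L2^2)``:
  Gaussians around both the direct point and the Hermitian point ``k' = -k``
  (a real image satisfies ``I~(-k) = conj(I~(k))``, so those two locations are
  strongly correlated), blended so that ``F_2 = 1`` exactly at both peaks and
  ``0 < F_2 <= 1`` everywhere.

The length scales ``L1``/``L2`` are the model's only hyperparameters; they
grow with library size and default to ``round(0.09 * N)`` grid units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .kspace import Grid
from .stats import LibraryStats

__all__ = [
    "KERNEL_KINDS",
    "EnvelopeKernel",
    "envelope_value",
    "envelope_matrix",
    "ModifiedCovariance",
    "apply_envelope",
    "default_length_scale",
    "tune_length_scale",
]

logger = logging.getLogger(__name__)

KERNEL_KINDS = ("unity", "delta", "single", "double")


def default_length_scale(N: int) -> float:
    """Grid-relative default length scale, ``max(1, round(0.09 N))``."""
    return float(max(1, round(0.09 * N)))


@dataclass(frozen=True)
class EnvelopeKernel:
    """Kernel choice plus length scale (``L1`` for single, ``L2`` for double)."""

    kind: str
    length_scale: float | None = None

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; expected one of {KERNEL_KINDS}")
        if self.kind in ("single", "double"):
            ls = self.length_scale
            if ls is None or not np.isfinite(ls) or ls <= 0:
                raise ValueError(f"{self.kind} kernel requires a finite positive length_scale")


def _pair_distances(A: np.ndarray, B: np.ndarray):
    """Squared distances ``|a - b|^2`` and ``|a + b|^2`` for all row pairs.

    Uses the expansion ``|a -/+ b|^2 = |a|^2 + |b|^2 -/+ 2 a.b`` so the same
    floating-point operations are performed for any sub-block of a grid,
    making lazily evaluated envelope blocks bit-identical to slices of the
    materialized matrix.
    """
    ra = np.einsum("ij,ij->i", A, A)
    rb = np.einsum("ij,ij->i", B, B)
    S = A @ B.T
    base = ra[:, None] + rb[None, :]
    return base - 2.0 * S, base + 2.0 * S


def envelope_matrix(kernel: EnvelopeKernel, coords_a, coords_b) -> np.ndarray:
    """Kernel values ``F(k, k')`` for all pairs of rows of two coordinate sets."""
    A = np.atleast_2d(np.asarray(coords_a, dtype=float))
    B = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if kernel.kind == "unity":
        return np.ones((A.shape[0], B.shape[0]))
    if kernel.kind == "delta":
        return (A[:, None, :] == B[None, :, :]).all(axis=-1).astype(float)
    L2sq = float(kernel.length_scale) ** 2
    d2_minus, d2_plus = _pair_distances(A, B)
    np.maximum(d2_minus, 0.0, out=d2_minus)
    if kernel.kind == "single":
        return np.exp(-d2_minus / L2sq)
    a = np.exp(-d2_minus / L2sq)
    b = np.exp(-d2_plus / L2sq)
    return (a + b) / (1.0 + a * b)


def envelope_value(kernel: EnvelopeKernel, k, k_prime) -> float:
    """Scalar ``F(k, k')`` for a single coordinate pair."""
    return float(envelope_matrix(kernel, [k], [k_prime])[0, 0])


class ModifiedCovariance:
    """Envelope-shaped covariances ``G' = K' . F`` and ``G'' = K'' . F``.

    Blocks can be materialized once (default, fastest for repeated slicing)
    or computed lazily per requested sub-block when memory is tight; the two
    paths are bit-identical.
    """

    def __init__(self, stats: LibraryStats, kernel: EnvelopeKernel, materialize: bool = True):
        self.kernel = kernel
        self.grid = stats.grid
        self._coords = self.grid.coords()
        self._K = {"re": stats.K_re, "im": stats.K_im}
        self._G: dict[str, np.ndarray] = {}
        if materialize:
            F = envelope_matrix(kernel, self._coords, self._coords)
            self._G["re"] = stats.K_re * F
            self._G["im"] = stats.K_im * F

    @property
    def N(self) -> int:
        return self.grid.N

    @property
    def materialized(self) -> bool:
        return bool(self._G)

    @property
    def G_re(self) -> np.ndarray:
        return self.block("re")

    @property
    def G_im(self) -> np.ndarray:
        return self.block("im")

    def block(self, channel: str, rows=None, cols=None) -> np.ndarray:
        """Sub-block ``G[rows, cols]`` of one channel (``None`` = all indices)."""
        if channel not in ("re", "im"):
            raise ValueError("channel must be 're' or 'im'")
        if channel in self._G:
            G = self._G[channel]
            if rows is None and cols is None:
                return G
            if rows is None:
                return G[:, cols]
            if cols is None:
                return G[rows, :]
            return G[np.ix_(np.asarray(rows), np.asarray(cols))]
        K = self._K[channel]
        ca = self._coords if rows is None else self._coords[np.asarray(rows)]
        cb = self._coords if cols is None else self._coords[np.asarray(cols)]
        if rows is None and cols is None:
            Kb = K
        elif rows is None:
            Kb = K[:, cols]
        elif cols is None:
            Kb = K[rows, :]
        else:
            Kb = K[np.ix_(np.asarray(rows), np.asarray(cols))]
        return Kb * envelope_matrix(self.kernel, ca, cb)

    def diag(self, channel: str) -> np.ndarray:
        """Diagonal of one channel (the envelope is 1 at ``k' = k``)."""
        if channel in self._G:
            return self._G[channel].diagonal()
        return self._K[channel].diagonal().copy()


def apply_envelope(
    stats: LibraryStats, kernel: EnvelopeKernel, materialize: bool = True
) -> ModifiedCovariance:
    """Shape the library covariances with an envelope kernel."""
    return ModifiedCovariance(stats, kernel, materialize=materialize)


def envelope_psd_check(kernel: EnvelopeKernel, N: int, tol_rel: float = 1e-10):
    """Empirical positive-semidefiniteness check of a kernel's Gram matrix.

    Returns ``(lam_min, lam_max, ok)`` for the kernel evaluated over all pixel
    pairs of an ``N x N`` grid; a failure is logged as a warning rather than
    raised — the double envelope in particular is symmetric and bounded but
    not provably PSD, and in practice carries small negative eigenvalues.
    """
    coords = Grid(N).coords()
    F = envelope_matrix(kernel, coords, coords)
    w = np.linalg.eigvalsh(F)
    lam_min, lam_max = float(w[0]), float(w[-1])
    ok = lam_min >= -tol_rel * max(lam_max, 0.0)
    if not ok:
        logger.warning(
            "envelope kernel %s (L=%s) is not PSD on a %dx%d grid: "
            "min eigenvalue %.3g (max %.3g)",
            kernel.kind,
            kernel.length_scale,
            N,
            N,
            lam_min,
            lam_max,
        )
    return lam_min, lam_max, ok


def tune_length_scale(
    stats: LibraryStats,
    tuning_images,
    kernel_kind: str,
    candidates,
    mask,
    pad_to: int | None = None,
) -> float:
    """Pick the length scale minimizing mean reconstruction NMSE.

    Each candidate builds an envelope covariance and reconstructs every tuning
    image (given as ``KSpaceData``) through the supplied sampling mask; the
    candidate with the smallest mean NMSE against the crop-limited reference
    wins, ties going to the smaller candidate. Candidates whose reconstruction
    fails are excluded with a warning.
    """
    from .kspace import from_kspace
    from .reconstruct import nmse, reconstruct, subsample

    cand = sorted(float(c) for c in candidates)
    if not cand:
        raise ValueError("candidate list must be non-empty")
    images = list(tuning_images)
    if not images:
        raise ValueError("tuning image collection must be non-empty")
    scores: list[tuple[float, float]] = []
    for L in cand:
        kernel = EnvelopeKernel(kernel_kind, L)
        cov = apply_envelope(stats, kernel)
        errs = []
        try:
            for k in images:
                pad = k.source_size if pad_to is None else pad_to
                obs = subsample(k, mask, stats.mean_magnitude)
                res = reconstruct(obs, mask, stats, cov, pad_to=pad)
                ref = from_kspace(k, pad_to=pad)
                errs.append(nmse(ref, res.image_star))
        except Exception as exc:  # noqa: BLE001 - candidate exclusion is the contract
            warnings.warn(f"length-scale candidate {L} failed and was excluded: {exc}")
            logger.warning("tune_length_scale: candidate %s excluded (%s)", L, exc)
            continue
        scores.append((float(np.mean(errs)), L))
    if not scores:
        raise RuntimeError("all length-scale candidates failed during tuning")
    scores.sort()  # by (mean NMSE, candidate); ties -> smaller candidate
    best = scores[0][1]
    logger.info("tune_length_scale(%s): chose L=%s from %s", kernel_kind, best, scores)
    return best
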