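"""Ring partition of k-space and Bayesian-optimization path selection.

k-space pixels are grouped into integer-radius annuli (``r = round(|k|)``,
half-away-from-zero, up to ``r_max = N/2``); pixels beyond ``r_max`` form the
corner set, which is never sampled and is inferred at reconstruction time.

Per-image path selection iterates: condition the Gaussian process on all
pixels sampled so far, evaluate the intensity-uncertainty acquisition
``sigma_I``, angularly average it over each still-unsampled ring, and sample
the ring with the largest average (ties to the smaller radius) — stopping
before any addition that would push the sampled-pixel count over the budget.

Per-image paths are aggregated into a generalized open-loop mask by taking
the most frequently selected radii that together fit the budget.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .kernels import ModifiedCovariance
from .kspace import Grid, KSpaceData
from .posterior import ObservationSet, intensity_uncertainty, posterior
from .stats import LibraryStats, normalize

__all__ = [
    "RingPartition",
    "SamplingMask",
    "PathTrace",
    "ring_partition",
    "angular_average",
    "select_path",
    "generalized_path",
    "ring_mask",
    "central_mask",
    "full_mask",
]


@dataclass
class RingPartition:
    """Disjoint integer-radius annuli covering an even ``N x N`` grid."""

    N: int
    rings: dict  # radius -> sorted flat indices
    corner_set: np.ndarray

    @property
    def r_max(self) -> int:
        return self.N // 2

    def basis(self, kind: str = "crop", full_size: int | None = None) -> int:
        """Pixel-budget basis: the crop grid (default) or the full image grid."""
        if kind == "crop":
            return self.N * self.N
        if kind == "full":
            if full_size is None:
                raise ValueError("budget basis 'full' requires full_size")
            return int(full_size) ** 2
        raise ValueError(f"unknown budget basis {kind!r}")


@dataclass
class SamplingMask:
    """Binary ring-union mask with its radii and sampled fraction."""

    mask: np.ndarray  # (N, N) uint8
    radii: list
    fraction: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        self.radii = sorted(int(r) for r in self.radii)

    @property
    def N(self) -> int:
        return self.mask.shape[0]

    @property
    def n_sampled(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class PathTrace:
    """Ordered radii selected for one image, with per-step ring averages."""

    radii: list
    tables: list = field(default_factory=list)  # per step: {radius: <sigma_I>_r}

    def __post_init__(self):
        if len(set(self.radii)) != len(self.radii):
            raise ValueError("trace radii must be unique")


def ring_partition(N: int) -> RingPartition:
    """Assign each pixel to ring ``round(|k|)`` (or the corner set beyond ``N/2``)."""
    grid = Grid(N)
    rho = grid.radius()
    r = np.floor(rho + 0.5).astype(int)  # half-away-from-zero for rho >= 0
    r_max = N // 2
    rings = {}
    for radius in range(r_max + 1):
        idx = np.flatnonzero(r == radius)
        if idx.size:
            rings[radius] = idx
    corner = np.flatnonzero(r > r_max)
    return RingPartition(N=N, rings=rings, corner_set=corner)


def angular_average(sigma_I, part: RingPartition) -> dict:
    """Arithmetic mean of ``sigma_I`` over each ring's pixels, as ``{r: value}``."""
    grid_vals = sigma_I.sigma_I if hasattr(sigma_I, "sigma_I") else np.asarray(sigma_I)
    if grid_vals.shape != (part.N, part.N):
        raise ValueError("field shape does not match the ring partition")
    flat = grid_vals.ravel()
    return {r: float(flat[idx].mean()) for r, idx in part.rings.items()}


def _budget_pixels(budget: float, basis: int) -> int:
    if not 0.0 <= budget <= 1.0:
        raise ValueError(f"budget must lie in [0, 1], got {budget}")
    return int(np.floor(budget * basis + 1e-9))


def select_path(
    image_k: KSpaceData,
    stats: LibraryStats,
    cov: ModifiedCovariance,
    part: RingPartition,
    budget: float,
    basis: int | None = None,
) -> PathTrace:
    """Greedy uncertainty-driven ring selection for one image."""
    if part.N != stats.N:
        raise ValueError("partition and stats disagree on grid size")
    basis = part.basis("crop") if basis is None else int(basis)
    budget_px = _budget_pixels(budget, basis)
    y_flat = normalize(image_k, stats.mean_magnitude).ravel()
    sampled_idx: list[np.ndarray] = []
    radii: list[int] = []
    tables: list[dict] = []
    count = 0
    remaining = set(part.rings)
    while remaining:
        idx = np.concatenate(sampled_idx) if sampled_idx else np.empty(0, dtype=int)
        obs = ObservationSet(indices=idx, values=y_flat[idx])
        fld = posterior(cov, stats, obs, want_variance=True)
        sig = intensity_uncertainty(fld, stats.mean_magnitude)
        avg = angular_average(sig, part)
        avg = {r: v for r, v in avg.items() if r in remaining}
        tables.append(avg)
        r_best = min(avg, key=lambda r: (-avg[r], r))
        ring_px = part.rings[r_best]
        if count + ring_px.size > budget_px:
            break
        radii.append(r_best)
        sampled_idx.append(ring_px)
        count += ring_px.size
        remaining.discard(r_best)
    return PathTrace(radii=radii, tables=tables)


def generalized_path(
    traces, part: RingPartition, budget: float, basis: int | None = None
) -> SamplingMask:
    """Aggregate per-image traces into a fixed open-loop ring mask.

    Radii are ranked by selection frequency (ties to the smaller radius) and
    added greedily while they fit the pixel budget; oversized rings are
    skipped and the scan continues down the list.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("trace collection must be non-empty")
    basis = part.basis("crop") if basis is None else int(basis)
    budget_px = _budget_pixels(budget, basis)
    freq = Counter()
    for tr in traces:
        freq.update(tr.radii)
    order = sorted(freq, key=lambda r: (-freq[r], r))
    chosen = []
    count = 0
    for r in order:
        size = part.rings[r].size
        if count + size <= budget_px:
            chosen.append(r)
            count += size
    return ring_mask(part, chosen, basis=basis)


def ring_mask(part: RingPartition, radii, basis: int | None = None) -> SamplingMask:
    """Build the binary mask that is the union of the given rings."""
    basis = part.basis("crop") if basis is None else int(basis)
    flat = np.zeros(part.N * part.N, dtype=np.uint8)
    for r in radii:
        flat[part.rings[int(r)]] = 1
    n_sampled = int(flat.sum())
    return SamplingMask(
        mask=flat.reshape(part.N, part.N),
        radii=list(radii),
        fraction=n_sampled / basis,
    )


def full_mask(part: RingPartition, basis: int | None = None) -> SamplingMask:
    """Mask covering every pixel (all rings plus the corner set).

    Represents full sampling (budget 1); the corner set, never reachable by
    ring selection, is included explicitly.
    """
    basis = part.basis("crop") if basis is None else int(basis)
    return SamplingMask(
        mask=np.ones((part.N, part.N), dtype=np.uint8),
        radii=sorted(part.rings),
        fraction=part.N * part.N / basis,
    )


def central_mask(part: RingPartition, budget: float, basis: int | None = None) -> SamplingMask:
    """Low-frequency-first ring mask (rings 0, 1, 2, ... while they fit).

    Used as a kernel-agnostic provisional mask, e.g. during length-scale
    tuning before any optimized path exists.
    """
    basis = part.basis("crop") if basis is None else int(basis)
    budget_px = _budget_pixels(budget, basis)
    chosen = []
    count = 0
    for r in sorted(part.rings):
        size = part.rings[r].size
        if count + size > budget_px:
            break
        chosen.append(r)
        count += size
    return ring_mask(part, chosen, basis=basis)
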