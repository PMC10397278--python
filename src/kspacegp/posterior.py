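"""Gaussian-process conditioning of the normalized k-space field.

Real and imaginary channels are conditioned independently on the sampled
pixels. With ``G`` an envelope-shaped covariance, observed flat indices
``1:m`` and values ``y``:

    mu(t)    = G(t, 1:m) G(1:m, 1:m)^-1 (y - mu0(1:m)) + mu0(t)
    sigma^2(t) = G(t, t) - G(t, 1:m) G(1:m, 1:m)^-1 G(1:m, t)

The ``m x m`` solve uses a Cholesky factorization with an adaptive diagonal
jitter ladder (0, then 1e-10 .. 1e-4 times the mean diagonal, escalating
tenfold) — empirical covariances are rank-deficient once ``m`` exceeds the
library size, so a bounded, documented jitter policy keeps results
reproducible.

The scalar acquisition field combines both channels into an uncertainty on
the unnormalized k-space intensity:

    sigma_I(k) = <|I~|>(k) sqrt(mu'^2 s'^2 + mu''^2 s''^2) / sqrt(mu'^2 + mu''^2)

with the convention ``sigma_I = 0`` where ``mu' = mu'' = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

from .kernels import ModifiedCovariance
from .stats import LibraryStats

__all__ = [
    "ObservationSet",
    "PosteriorField",
    "UncertaintyField",
    "SingularCovarianceError",
    "posterior",
    "intensity_uncertainty",
    "brute_force_conditional",
]

#: jitter ladder bounds, relative to the mean diagonal of the observed block
JITTER_START = 1e-10
JITTER_MAX = 1e-4
#: negative variances within -NEG_VAR_ROUNDOFF x max(1, max prior diag) are
#: silently clipped as round-off; up to -NEG_VAR_GUARD they are clipped with a
#: logged warning (the double envelope is only empirically positive
#: semi-definite, so small genuine negatives occur); beyond that it is an error
NEG_VAR_ROUNDOFF = 1e-9
NEG_VAR_GUARD = 0.05
#: relative eigenvalue cutoff (rcond) of the truncated rescue solver; weak
#: directions couple to the full shaped covariance's indefiniteness and
#: amplify when inverted
EIG_TRUNC_REL = 1e-5


class SingularCovarianceError(np.linalg.LinAlgError):
    """Raised when a channel's observed covariance block cannot be factorized
    even after jitter escalation."""


@dataclass
class ObservationSet:
    """Sampled flat pixel indices and their normalized complex values."""

    indices: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int).ravel()
        self.values = np.asarray(self.values, dtype=complex).ravel()
        if self.indices.shape != self.values.shape:
            raise ValueError("indices and values must have equal length")
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("observation indices must be unique")

    @property
    def m(self) -> int:
        return self.indices.size


@dataclass
class PosteriorField:
    """Per-pixel posterior means and variances of both channels."""

    mu_re: np.ndarray
    mu_im: np.ndarray
    var_re: np.ndarray
    var_im: np.ndarray
    jitter_used: float = 0.0


@dataclass
class UncertaintyField:
    """Scalar intensity-uncertainty acquisition field ``sigma_I >= 0``."""

    sigma_I: np.ndarray


def _jitter_ladder(base: float):
    yield 0.0
    level = JITTER_START
    while level <= JITTER_MAX * (1 + 1e-12):
        yield level * base
        level *= 10.0


def _condition(
    cov: ModifiedCovariance,
    channel: str,
    mu0: np.ndarray,
    idx: np.ndarray,
    vals: np.ndarray,
    want_variance: bool,
):
    m = idx.size
    prior_diag = cov.diag(channel)
    if m == 0:
        var = prior_diag.copy() if want_variance else None
        return mu0.copy(), var, 0.0
    Gmm = np.asarray(cov.block(channel, idx, idx), dtype=float)
    cross = cov.block(channel, None, idx)  # (N^2, m)
    scale = max(1.0, float(prior_diag.max(initial=0.0)))

    def _apply(solve, jitter_used):
        alpha = solve(vals - mu0[idx])
        mu = cross @ alpha + mu0
        var = None
        if want_variance:
            V = solve(np.ascontiguousarray(cross.T))
            var = prior_diag - np.einsum("ij,ji->i", cross, V)
        return mu, var, jitter_used

    result = None
    solve = _cholesky_solver(Gmm, m)
    if solve is not None:
        result = _apply(*solve)
        if want_variance and float(result[1].min()) < -NEG_VAR_GUARD * scale:
            # A barely positive-definite factorization of an indefinite block
            # amplified its noise directions; fall through to the truncated
            # eigensolve.
            result = None
    if result is None:
        result = _apply(*_truncated_eig_solver(Gmm, m, channel))
    mu, var, jitter_used = result
    if want_variance:
        worst = float(var.min(initial=0.0))
        if worst < -NEG_VAR_GUARD * scale:
            raise FloatingPointError(
                f"posterior variance of channel {channel!r} reached {worst}, "
                f"far below the indefiniteness guard {-NEG_VAR_GUARD * scale}"
            )
        if worst < -NEG_VAR_ROUNDOFF * scale:
            logger.debug(
                "clipping negative posterior variance %.3g in channel %r "
                "(envelope-shaped covariance is not exactly PSD)",
                worst,
                channel,
            )
        np.clip(var, 0.0, None, out=var)
    return mu, var, jitter_used


def _cholesky_solver(Gmm: np.ndarray, m: int):
    """Cholesky factorization with the adaptive jitter ladder; ``None`` if the
    whole ladder fails."""
    A = np.array(Gmm, copy=True)
    diag_mean = float(A.diagonal().mean())
    base = diag_mean if diag_mean > 0 else 1.0
    prev = 0.0
    for jit in _jitter_ladder(base):
        A.flat[:: m + 1] += jit - prev
        prev = jit
        try:
            factor = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            continue
        return (lambda B: cho_solve(factor, B)), jit
    return None


def _truncated_eig_solver(Gmm: np.ndarray, m: int, channel: str):
    """Pseudo-inverse through a truncated eigendecomposition.

    The envelope-shaped block can be genuinely indefinite (the double
    envelope is only empirically PSD); discarding non-positive and near-null
    directions conditions on the reliable subspace instead of amplifying
    noise. The returned regularization strength is the magnitude of the most
    negative eigenvalue.
    """
    w, U = np.linalg.eigh(Gmm)
    top = float(w.max(initial=0.0))
    if top <= 0:
        raise SingularCovarianceError(
            f"covariance block of channel {channel!r} (m={m}) has no positive "
            "eigenvalues; cannot condition on these observations"
        )
    # keep only directions clearly above both round-off and the measured
    # indefiniteness scale; weaker ones are noise and amplify when inverted
    keep = w > max(EIG_TRUNC_REL * top, 10.0 * abs(min(float(w[0]), 0.0)))
    Uk = np.ascontiguousarray(U[:, keep])
    wk = w[keep]
    logger.debug(
        "channel %r (m=%d): truncated eigensolve kept %d/%d directions "
        "(min eigenvalue %.3g)",
        channel,
        m,
        int(keep.sum()),
        m,
        float(w[0]),
    )

    def solve(B, _Uk=Uk, _wk=wk):
        return _Uk @ ((_Uk.T @ B).T / _wk).T

    return solve, float(max(0.0, -w[0]))


def posterior(
    cov: ModifiedCovariance,
    stats: LibraryStats,
    obs: ObservationSet,
    want_variance: bool = True,
) -> PosteriorField:
    """Condition both channels of the normalized field on the observations.

    With no observations the prior is returned (means ``mu0``, variances the
    covariance diagonals). ``want_variance=False`` skips the quadratic-form
    term, which reconstruction does not need.
    """
    N = stats.N
    idx = obs.indices
    if idx.size and (idx.min() < 0 or idx.max() >= N * N):
        raise ValueError("observation indices outside the grid")
    mu_r, var_r, j_r = _condition(cov, "re", stats.mu0_re, idx, obs.values.real, want_variance)
    mu_i, var_i, j_i = _condition(cov, "im", stats.mu0_im, idx, obs.values.imag, want_variance)
    shape = (N, N)
    return PosteriorField(
        mu_re=mu_r.reshape(shape),
        mu_im=mu_i.reshape(shape),
        var_re=var_r.reshape(shape) if var_r is not None else None,
        var_im=var_i.reshape(shape) if var_i is not None else None,
        jitter_used=max(j_r, j_i),
    )


def intensity_uncertainty(field: PosteriorField, mean_magnitude: np.ndarray) -> UncertaintyField:
    """Scalar acquisition field on the unnormalized intensity scale."""
    mm = np.asarray(mean_magnitude, dtype=float)
    if field.var_re is None or field.var_im is None:
        raise ValueError("posterior field lacks variances; rerun with want_variance=True")
    if mm.shape != field.mu_re.shape:
        raise ValueError("mean_magnitude shape does not match the posterior field")
    mr2 = field.mu_re**2
    mi2 = field.mu_im**2
    denom2 = mr2 + mi2
    num = np.sqrt(mr2 * field.var_re + mi2 * field.var_im)
    sigma = np.zeros_like(num)
    nz = denom2 > 0
    sigma[nz] = mm[nz] * num[nz] / np.sqrt(denom2[nz])
    return UncertaintyField(sigma_I=sigma)


def brute_force_conditional(prior_mean: np.ndarray, prior_cov: np.ndarray, obs: ObservationSet):
    """Textbook conditional Gaussian by direct block inversion (test oracle).

    Returns the full-size conditional mean vector and covariance matrix:
    observed entries carry the observed values with zero (co)variance.
    Intended for tiny problems only.
    """
    mean = np.asarray(prior_mean, dtype=float).copy()
    cov = np.asarray(prior_cov, dtype=float)
    n = mean.size
    if cov.shape != (n, n):
        raise ValueError("prior covariance shape mismatch")
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise ValueError("prior covariance must be symmetric")
    try:
        np.linalg.cholesky(cov + 0.0)
    except np.linalg.LinAlgError as exc:
        raise ValueError("prior covariance must be positive definite") from exc
    idx = obs.indices
    if idx.size == 0:
        return mean, cov.copy()
    vals = obs.values.real if np.iscomplexobj(obs.values) else np.asarray(obs.values, float)
    unobs = np.setdiff1d(np.arange(n), idx)
    out_mean = np.zeros(n)
    out_cov = np.zeros((n, n))
    out_mean[idx] = vals
    if unobs.size:
        S_oo = cov[np.ix_(idx, idx)]
        S_uo = cov[np.ix_(unobs, idx)]
        S_uu = cov[np.ix_(unobs, unobs)]
        w = np.linalg.solve(S_oo, vals - mean[idx])
        out_mean[unobs] = mean[unobs] + S_uo @ w
        out_cov[np.ix_(unobs, unobs)] = S_uu - S_uo @ np.linalg.solve(S_oo, S_uo.T)
    return out_mean, out_cov
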