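import numpy as np
import pytest

import kspacegp as kg
from conftest import random_pd_stats
from kspacegp.kernels import EnvelopeKernel, apply_envelope
from kspacegp.posterior import (
    ObservationSet,
    brute_force_conditional,
    intensity_uncertainty,
    posterior,
)


def test_observation_set_validation():
    with pytest.raises(ValueError):
        ObservationSet([1, 1], [1.0, 2.0])
    with pytest.raises(ValueError):
        ObservationSet([1, 2], [1.0])
    assert ObservationSet([], []).m == 0


def test_no_observations_returns_prior(rng):
    stats = random_pd_stats(4, rng)
    cov = apply_envelope(stats, EnvelopeKernel("unity"))
    fld = posterior(cov, stats, ObservationSet([], []))
    np.testing.assert_array_equal(fld.mu_re.ravel(), stats.mu0_re)
    np.testing.assert_array_equal(fld.mu_im.ravel(), stats.mu0_im)
    np.testing.assert_array_equal(fld.var_re.ravel(), np.diag(stats.K_re))
    np.testing.assert_array_equal(fld.var_im.ravel(), np.diag(stats.K_im))


def test_posterior_interpolates_observed_pixels(rng):
    stats = random_pd_stats(4, rng)
    cov = apply_envelope(stats, EnvelopeKernel("unity"))
    idx = np.array([1, 7, 12])
    vals = rng.standard_normal(3) + 1j * rng.standard_normal(3)
    fld = posterior(cov, stats, ObservationSet(idx, vals))
    np.testing.assert_allclose(fld.mu_re.ravel()[idx], vals.real, atol=1e-8)
    np.testing.assert_allclose(fld.mu_im.ravel()[idx], vals.imag, atol=1e-8)
    assert np.all(fld.var_re.ravel()[idx] <= 1e-6 * np.diag(stats.K_re)[idx])


def test_posterior_matches_brute_force_oracle(rng):
    stats = random_pd_stats(4, rng)
    cov = apply_envelope(stats, EnvelopeKernel("unity"))
    idx = np.array([0, 3, 9])
    vals = rng.standard_normal(3) + 1j * rng.standard_normal(3)
    fld = posterior(cov, stats, ObservationSet(idx, vals))
    mean_re, cov_re = brute_force_conditional(
        stats.mu0_re, stats.K_re, ObservationSet(idx, vals.real)
    )
    np.testing.assert_allclose(fld.mu_re.ravel(), mean_re, atol=1e-8)
    np.testing.assert_allclose(fld.var_re.ravel(), np.diag(cov_re), atol=1e-8)


def test_posterior_order_invariance(rng):
    stats = random_pd_stats(4, rng)
    cov = apply_envelope(stats, EnvelopeKernel("unity"))
    idx = np.array([2, 5, 11, 14])
    vals = rng.standard_normal(4) + 1j * rng.standard_normal(4)
    a = posterior(cov, stats, ObservationSet(idx, vals))
    perm = np.array([3, 0, 2, 1])
    b = posterior(cov, stats, ObservationSet(idx[perm], vals[perm]))
    np.testing.assert_allclose(a.mu_re, b.mu_re, atol=1e-10)
    np.testing.assert_allclose(a.var_re, b.var_re, atol=1e-10)


def test_channels_conditioned_independently(rng):
    stats = random_pd_stats(4, rng)
    cov = apply_envelope(stats, EnvelopeKernel("unity"))
    idx = np.array([4, 8])
    re = rng.standard_normal(2)
    a = posterior(cov, stats, ObservationSet(idx, re + 1j * rng.standard_normal(2)))
    b = posterior(cov, stats, ObservationSet(idx, re + 1j * rng.standard_normal(2)))
    np.testing.assert_array_equal(a.mu_re, b.mu_re)
    np.testing.assert_array_equal(a.var_re, b.var_re)
    assert np.any(a.mu_im != b.mu_im)


def test_variance_contracts_as_observations_accumulate(rng):
    stats = random_pd_stats(4, rng)
    cov = apply_envelope(stats, EnvelopeKernel("unity"))
    all_idx = rng.permutation(16)
    vals = rng.standard_normal(16) + 0j
    prev = None
    for m in (0, 3, 7, 12, 16):
        fld = posterior(cov, stats, ObservationSet(all_idx[:m], vals[:m]))
        if prev is not None:
            assert np.all(fld.var_re <= prev + 1e-8)
        prev = fld.var_re


def test_out_of_grid_indices_rejected(rng):
    stats = random_pd_stats(2, rng)
    cov = apply_envelope(stats, EnvelopeKernel("unity"))
    with pytest.raises(ValueError):
        posterior(cov, stats, ObservationSet([4], [1.0]))


class TestBruteForceConditional:
    def test_no_observations_unchanged(self):
        mean = np.array([1.0, 2.0])
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        m, c = brute_force_conditional(mean, cov, ObservationSet([], []))
        np.testing.assert_array_equal(m, mean)
        np.testing.assert_array_equal(c, cov)

    def test_fully_observed_collapses(self):
        mean = np.zeros(3)
        cov = np.eye(3)
        obs = ObservationSet([0, 1, 2], [1.0, -2.0, 0.5])
        m, c = brute_force_conditional(mean, cov, obs)
        np.testing.assert_array_equal(m, [1.0, -2.0, 0.5])
        np.testing.assert_array_equal(c, np.zeros((3, 3)))

    def test_two_point_closed_form(self):
        rho, v = 0.6, 1.7
        cov = np.array([[1.0, rho], [rho, 1.0]])
        m, c = brute_force_conditional(np.zeros(2), cov, ObservationSet([1], [v]))
        assert m[0] == pytest.approx(rho * v)
        assert c[0, 0] == pytest.approx(1 - rho**2)

    def test_non_pd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError):
            brute_force_conditional(np.zeros(2), bad, ObservationSet([0], [1.0]))


class TestIntensityUncertainty:
    def test_zero_variance_gives_zero_uncertainty(self, rng):
        stats = random_pd_stats(2, rng)
        fld = kg.PosteriorField(
            mu_re=rng.standard_normal((2, 2)),
            mu_im=rng.standard_normal((2, 2)),
            var_re=np.zeros((2, 2)),
            var_im=np.zeros((2, 2)),
        )
        unc = intensity_uncertainty(fld, stats.mean_magnitude)
        np.testing.assert_array_equal(unc.sigma_I, np.zeros((2, 2)))

    def test_single_channel_cancellation(self):
        """With mu''=0 the mu' factors cancel: sigma_I = <I~> * sigma'."""
        mm = np.full((2, 2), 3.0)
        s = 0.25
        fld = kg.PosteriorField(
            mu_re=np.full((2, 2), 1.7),
            mu_im=np.zeros((2, 2)),
            var_re=np.full((2, 2), s**2),
            var_im=np.full((2, 2), 9.9),
        )
        unc = intensity_uncertainty(fld, mm)
        np.testing.assert_allclose(unc.sigma_I, mm * s, rtol=1e-12)

    def test_zero_mean_pixels_use_limit_convention(self):
        mm = np.ones((2, 2))
        fld = kg.PosteriorField(
            mu_re=np.zeros((2, 2)),
            mu_im=np.zeros((2, 2)),
            var_re=np.ones((2, 2)),
            var_im=np.ones((2, 2)),
        )
        np.testing.assert_array_equal(
            intensity_uncertainty(fld, mm).sigma_I, np.zeros((2, 2))
        )

    def test_matches_elementwise_formula_oracle(self, rng):
        mm = rng.uniform(0.5, 2.0, (3, 3))
        fld = kg.PosteriorField(
            mu_re=rng.standard_normal((3, 3)),
            mu_im=rng.standard_normal((3, 3)),
            var_re=rng.uniform(0, 1, (3, 3)),
            var_im=rng.uniform(0, 1, (3, 3)),
        )
        unc = intensity_uncertainty(fld, mm)
        for i in range(3):
            for j in range(3):
                mr, mi = fld.mu_re[i, j], fld.mu_im[i, j]
                vr, vi = fld.var_re[i, j], fld.var_im[i, j]
                expect = mm[i, j] * np.sqrt(mr**2 * vr + mi**2 * vi) / np.sqrt(mr**2 + mi**2)
                assert unc.sigma_I[i, j] == pytest.approx(expect, abs=1e-12)
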