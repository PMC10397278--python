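import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kspacegp as kg
from kspacegp.kernels import (
    EnvelopeKernel,
    apply_envelope,
    envelope_matrix,
    envelope_value,
    tune_length_scale,
)

coord = st.tuples(
    st.integers(min_value=-32, max_value=32), st.integers(min_value=-32, max_value=32)
)


def test_unity_and_delta_values():
    u = EnvelopeKernel("unity")
    d = EnvelopeKernel("delta")
    assert envelope_value(u, (3, -5), (12, 7)) == 1.0
    assert envelope_value(d, (3, -5), (3, -5)) == 1.0
    assert envelope_value(d, (3, -5), (3, -4)) == 0.0


def test_single_envelope_at_one_length_scale():
    k = EnvelopeKernel("single", 5.0)
    # |k - k'| = 5 via a 3-4-5 triangle
    assert envelope_value(k, (0, 0), (3, 4)) == pytest.approx(np.exp(-1.0))


def test_double_envelope_unity_at_direct_and_hermitian_points():
    k = EnvelopeKernel("double", 4.0)
    for pt in [(0, 0), (3, -5), (-7, 2), (10, 10)]:
        assert envelope_value(k, pt, pt) == 1.0
        assert envelope_value(k, pt, (-pt[0], -pt[1])) == 1.0


@settings(derandomize=True, max_examples=50)
@given(a=coord, b=coord)
def test_kernel_symmetry_and_bounds(a, b):
    for kernel in (
        EnvelopeKernel("unity"),
        EnvelopeKernel("delta"),
        EnvelopeKernel("single", 6.0),
        EnvelopeKernel("double", 6.0),
    ):
        fab = envelope_value(kernel, a, b)
        assert fab == envelope_value(kernel, b, a)
        assert 0.0 <= fab <= 1.0
        if kernel.kind in ("single", "double"):
            assert fab > 0.0


@settings(derandomize=True, max_examples=50)
@given(a=coord, b=coord)
def test_double_envelope_hermitian_pair_symmetry(a, b):
    k = EnvelopeKernel("double", 5.0)
    na, nb = (-a[0], -a[1]), (-b[0], -b[1])
    assert envelope_value(k, a, b) == pytest.approx(envelope_value(k, na, nb), rel=1e-12)


def test_single_envelope_strictly_decreasing_in_distance():
    k = EnvelopeKernel("single", 4.0)
    vals = [envelope_value(k, (0, 0), (0, j)) for j in range(10)]
    assert all(x > y for x, y in zip(vals, vals[1:]))


def test_envelope_psd_check_flags_double_and_passes_single(caplog):
    """PSD-ness of the envelopes is checked empirically, not guaranteed: the
    Gaussian single envelope is PSD, while the double envelope carries small
    negative eigenvalues that are logged as a warning."""
    import logging

    from kspacegp.kernels import envelope_psd_check

    lam_min, lam_max, ok = envelope_psd_check(EnvelopeKernel("single", 2.0), 4)
    assert ok and lam_max > 0
    with caplog.at_level(logging.WARNING, logger="kspacegp.kernels"):
        lam_min, lam_max, ok = envelope_psd_check(EnvelopeKernel("double", 2.0), 4)
    assert not ok and lam_min < 0
    assert any("not PSD" in rec.message for rec in caplog.records)


def test_invalid_kernels_rejected():
    with pytest.raises(ValueError):
        EnvelopeKernel("gauss")
    with pytest.raises(ValueError):
        EnvelopeKernel("single")
    with pytest.raises(ValueError):
        EnvelopeKernel("double", -2.0)


def _toy_stats(N=4, seed=0):
    lib = kg.generate_library(6, kg.PhantomSpec(grid_size_full=2 * N), seed, (6, 0, 0))
    return kg.compute_prior_stats([kg.to_kspace(im, N) for im in lib.images])


def test_apply_envelope_unity_is_bitwise_identity():
    stats = _toy_stats()
    cov = apply_envelope(stats, EnvelopeKernel("unity"))
    np.testing.assert_array_equal(cov.G_re, stats.K_re)
    np.testing.assert_array_equal(cov.G_im, stats.K_im)


def test_apply_envelope_delta_keeps_only_diagonal():
    stats = _toy_stats()
    cov = apply_envelope(stats, EnvelopeKernel("delta"))
    np.testing.assert_array_equal(np.diag(cov.G_re), np.diag(stats.K_re))
    off = ~np.eye(stats.N**2, dtype=bool)
    assert np.all(cov.G_re[off] == 0)


def test_apply_envelope_matches_elementwise_oracle():
    stats = _toy_stats()
    kernel = EnvelopeKernel("double", 3.0)
    cov = apply_envelope(stats, kernel)
    coords = stats.grid.coords()
    for t in range(stats.N**2):
        for u in range(stats.N**2):
            f = envelope_value(kernel, coords[t], coords[u])
            assert cov.G_re[t, u] == pytest.approx(stats.K_re[t, u] * f, abs=1e-14)
            assert cov.G_im[t, u] == pytest.approx(stats.K_im[t, u] * f, abs=1e-14)


def test_lazy_blocks_bit_identical_to_materialized():
    stats = _toy_stats(N=6)
    kernel = EnvelopeKernel("double", 3.0)
    full = apply_envelope(stats, kernel, materialize=True)
    lazy = apply_envelope(stats, kernel, materialize=False)
    rows = np.array([0, 5, 17, 30])
    cols = np.array([2, 3, 11])
    for ch in ("re", "im"):
        np.testing.assert_array_equal(
            lazy.block(ch, rows, cols), full.block(ch, rows, cols)
        )
        np.testing.assert_array_equal(lazy.block(ch), full.block(ch))
        np.testing.assert_array_equal(lazy.diag(ch), full.diag(ch))


@pytest.fixture(scope="module")
def tuning_setup():
    lib = kg.generate_library(46, kg.PhantomSpec(grid_size_full=24), 6, (40, 6, 0))
    stats = kg.KSpaceGP(crop_size=16, kernel="unity").fit(lib.subset("stats")).stats_
    part = kg.ring_partition(16)
    mask = kg.central_mask(part, 0.2)
    kdata = [kg.to_kspace(im, 16) for im in lib.subset("path")]
    return stats, kdata, mask


class TestTuneLengthScale:
    def test_singleton_candidate_returned(self, tuning_setup):
        stats, kdata, mask = tuning_setup
        assert tune_length_scale(stats, kdata, "single", [3.5], mask) == 3.5

    def test_choice_matches_exhaustive_reevaluation(self, tuning_setup):
        """The tuned length scale equals the argmin found by independently
        reconstructing every tuning image under every candidate."""
        from kspacegp.kspace import from_kspace
        from kspacegp.reconstruct import nmse, reconstruct, subsample

        stats, kdata, mask = tuning_setup
        candidates = [2.0, 4.0, 8.0]
        chosen = tune_length_scale(stats, kdata, "single", candidates, mask, pad_to=24)
        means = {}
        for L in candidates:
            cov = apply_envelope(stats, EnvelopeKernel("single", L))
            errs = []
            for k in kdata:
                obs = subsample(k, mask, stats.mean_magnitude)
                res = reconstruct(obs, mask, stats, cov, pad_to=24)
                errs.append(nmse(from_kspace(k, 24), res.image_star))
            means[L] = np.mean(errs)
        assert chosen == min(candidates, key=lambda L: (means[L], L))
        assert chosen in candidates

    def test_empty_candidates_rejected(self, tuning_setup):
        stats, kdata, mask = tuning_setup
        with pytest.raises(ValueError):
            tune_length_scale(stats, kdata, "single", [], mask)
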