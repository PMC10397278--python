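import numpy as np
import pytest

import kspacegp as kg


@pytest.fixture(scope="session")
def small_cohort():
    """Small phantom cohort with fitted prior (N0=40, crop 32, n1=26)."""
    spec = kg.PhantomSpec(grid_size_full=40)
    lib = kg.generate_library(30, spec, 1, (26, 2, 2))
    stats = kg.KSpaceGP(crop_size=32, kernel="unity").fit(lib.subset("stats")).stats_
    return lib, stats


@pytest.fixture(scope="session")
def study_cohort():
    """Acceptance-scale cohort (N0=80, crop 64, split 400/20/40) with prior."""
    spec = kg.PhantomSpec(grid_size_full=80)
    lib = kg.generate_library(460, spec, 1, (400, 20, 40))
    stats = kg.KSpaceGP(crop_size=64, kernel="unity").fit(lib.subset("stats")).stats_
    return lib, stats


@pytest.fixture(scope="session")
def study_results(study_cohort):
    """Kernel-comparison study shared by the ordering/monotonicity checks."""
    from kspacegp.experiments import kernel_comparison_study

    lib, stats = study_cohort
    return kernel_comparison_study(seed=1, library=lib, stats=stats)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_pd_stats(N: int, rng: np.random.Generator) -> kg.LibraryStats:
    """LibraryStats with random well-conditioned PD covariances (test helper)."""
    n2 = N * N
    A = rng.standard_normal((n2, n2))
    B = rng.standard_normal((n2, n2))
    return kg.LibraryStats(
        mean_magnitude=rng.uniform(0.5, 2.0, (N, N)),
        mu0_re=rng.standard_normal(n2),
        mu0_im=rng.standard_normal(n2),
        K_re=A @ A.T / n2 + 0.5 * np.eye(n2),
        K_im=B @ B.T / n2 + 0.5 * np.eye(n2),
        n1=50,
    )
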