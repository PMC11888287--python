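"""Shared fixtures: small synthetic cohorts and pre-built sampling machinery."""

import numpy as np
import pytest

from lipoinfer import (
    CohortSpec,
    CurvePool,
    QuasiPeriodicGP,
    T_ALL,
    T_POST20,
    fit_lognormal,
    make_cohort,
)


@pytest.fixture(scope="session")
def cohort_2d():
    """21 noisy two-state-model subjects with hidden truth."""
    return make_cohort(CohortSpec(model_id="2d", n_subjects=21, seed=11))


@pytest.fixture(scope="session")
def cohort_3d():
    return make_cohort(CohortSpec(model_id="3d", n_subjects=21, seed=12))


@pytest.fixture(scope="session")
def noiseless_cohort_2d():
    """10 noise-free subjects for optimizer recovery experiments."""
    return make_cohort(CohortSpec(model_id="2d", n_subjects=10, noise_sd=0.0,
                                  seed=21))


@pytest.fixture(scope="session")
def dist_2d(cohort_2d):
    """Log-normal parameter model fitted to the 2D cohort's hidden truth."""
    _, truth = cohort_2d
    return fit_lognormal(truth)


@pytest.fixture(scope="session")
def dist_3d(cohort_3d):
    _, truth = cohort_3d
    return fit_lognormal(truth)


@pytest.fixture(scope="session")
def gp_pools_2d(cohort_2d):
    """Insulin and glucose curve pools from briefly-fitted GPs (full grid)."""
    records, _ = cohort_2d
    gp_i = QuasiPeriodicGP(max_iter=60, seed=0).fit(
        np.stack([r.I for r in records]), t=T_ALL)
    gp_g = QuasiPeriodicGP(max_iter=60, seed=0).fit(
        np.stack([r.G for r in records]), t=T_ALL)
    return gp_i, gp_g


@pytest.fixture()
def pools_2d(gp_pools_2d):
    """Fresh (unused) pools per test."""
    gp_i, gp_g = gp_pools_2d
    return (CurvePool(gp_i.sample(6000, seed=5)),
            CurvePool(gp_g.sample(6000, seed=6)))


@pytest.fixture(scope="session")
def small_dataset_2d(dist_2d, gp_pools_2d):
    """A ~1500-row labelled 2D dataset shared by feature/training tests."""
    from lipoinfer import generate_dataset
    gp_i, gp_g = gp_pools_2d
    pool = CurvePool(gp_i.sample(5000, seed=7))
    gpool = CurvePool(gp_g.sample(5000, seed=8))
    return generate_dataset(dist_2d, pool, 1500, "2d", seed=9,
                            glucose_pool=gpool)


@pytest.fixture(scope="session")
def small_dataset_3d(dist_3d, cohort_3d):
    from lipoinfer import generate_dataset
    records, _ = cohort_3d
    gp = QuasiPeriodicGP(max_iter=60, seed=0).fit(
        np.stack([r.I[T_ALL > 20] for r in records]), t=T_POST20)
    pool = CurvePool(gp.sample(4000, seed=7))
    return generate_dataset(dist_3d, pool, 800, "3d", seed=9)
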