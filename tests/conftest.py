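"""Shared fixtures: small synthetic cohorts and geometries.

All fixtures are generated programmatically with fixed seeds; expensive
cohort-level fixtures are session-scoped so the pipeline runs once.
"""

import numpy as np
import pytest

import whalign as wa


@pytest.fixture(scope="session")
def grid6():
    """6 x 6 grid, 3 mm spacing (36 vertices)."""
    return wa.grid_geometry(6, 6, spacing_mm=3.0)


@pytest.fixture(scope="session")
def small_spec():
    return wa.CohortSpec(n_subjects=4, t_time=160, v_vertex=36, k_latent=6,
                         noise_sd=1.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return wa.make_cohort(small_spec)


@pytest.fixture(scope="session")
def noiseless_cohort():
    spec = wa.CohortSpec(n_subjects=4, t_time=160, v_vertex=36, k_latent=6,
                         noise_sd=0.0, seed=7)
    return wa.make_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_splithalf(noiseless_cohort):
    """Full pipeline split-half analysis on the noiseless cohort."""
    cohort, truth = noiseless_cohort
    cfg = wa.ExperimentConfig(radius_mm=8.0, seed=7)
    return wa.split_half_tuning_analysis(cohort, truth.geometry, cfg), truth


@pytest.fixture(scope="session")
def noisy_splithalf(small_cohort):
    """Full pipeline split-half analysis on the moderate-noise cohort."""
    cohort, truth = small_cohort
    cfg = wa.ExperimentConfig(radius_mm=8.0, seed=11)
    return wa.split_half_tuning_analysis(cohort, truth.geometry, cfg), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
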