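"""Shared fixtures: analytic surface pairs and synthetic cohorts."""

import numpy as np
import pytest

from fetalsp.cohort import CohortConfig, generate_cohort
from fetalsp.synthsurf import generate_surface_pair


@pytest.fixture(scope="session")
def sphere_pair():
    """Concentric spheres R=25, r=23 (thickness exactly 2 mm)."""
    return generate_surface_pair(radius=25.0, amplitude=0.0,
                                 thickness_field=2.0, subdivisions=4)


@pytest.fixture(scope="session")
def perturbed_pair():
    """Degree-6 harmonic perturbation, amplitude 3 mm, on a 30 mm sphere."""
    return generate_surface_pair(radius=30.0, amplitude=3.0, harmonic_degree=6,
                                 thickness_field=2.0, subdivisions=4, seed=1)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-condition cohort (68 subjects, 10% CV, 3% outliers)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Same cohort with all noise, size jitter, and outliers switched off."""
    return generate_cohort(CohortConfig(seed=11).noiseless())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
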