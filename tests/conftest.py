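import numpy as np
import pytest

from facemasc.geodesic import GeodesicSolver
from facemasc.synthetic import (CohortConfig, FeatureTableConfig,
                                fixture_mesh, generate_cohort,
                                generate_feature_table)
from facemasc.template import template_landmarks, template_mesh


@pytest.fixture(scope="session")
def plane():
    return fixture_mesh("plane")


@pytest.fixture(scope="session")
def plane_solver(plane):
    return GeodesicSolver(plane)


@pytest.fixture(scope="session")
def sphere():
    return fixture_mesh("unit_sphere")


@pytest.fixture(scope="session")
def sphere_solver(sphere):
    return GeodesicSolver(sphere)


@pytest.fixture(scope="session")
def face_mesh():
    return template_mesh()


@pytest.fixture(scope="session")
def face_solver(face_mesh):
    return GeodesicSolver(face_mesh)


@pytest.fixture(scope="session")
def female_landmarks():
    return template_landmarks("female")


@pytest.fixture(scope="session")
def feature_table():
    """One calibrated 355-subject cohort feature table (seed 0)."""
    table, records = generate_feature_table(FeatureTableConfig(), seed=0)
    return table


@pytest.fixture(scope="session")
def small_cohort():
    """Small landmark-level cohort for geometry-route tests."""
    config = CohortConfig(
        group_sizes={("male", "autism_parent"): 4,
                     ("female", "autism_parent"): 4,
                     ("male", "comparison_parent"): 4,
                     ("female", "comparison_parent"): 4},
        seed=11,
    )
    return generate_cohort(config)
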