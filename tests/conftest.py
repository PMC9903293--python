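"""Shared fixtures: meshes, protocol, simulated phantom frames, Jacobians.

Everything is generated at test time; session scope keeps the FEM solves to
one per configuration.
"""

import warnings

import numpy as np
import pytest

from eitsep import (
    PhantomSpec, adjacent_protocol, assign_phantom, build_mesh,
    compute_jacobian, solve_forward,
)

warnings.filterwarnings("ignore", message="lung inclusions overlap")


@pytest.fixture(scope="session")
def protocol():
    return adjacent_protocol(16)


@pytest.fixture(scope="session")
def mesh2d():
    return build_mesh(dimension=2, n_electrodes=16, target_element_size=0.08)


@pytest.fixture(scope="session")
def mesh2d_coarse():
    return build_mesh(dimension=2, n_electrodes=16, target_element_size=0.25)


@pytest.fixture(scope="session")
def mesh3d():
    return build_mesh(dimension=3, n_electrodes=16, target_element_size=0.15,
                      height=1.0)


@pytest.fixture(scope="session")
def jac2d(mesh2d, protocol):
    return compute_jacobian(mesh2d, protocol=protocol)


@pytest.fixture(scope="session")
def homog_frame2d(jac2d):
    return jac2d.reference_frame


@pytest.fixture(scope="session")
def phantom_frames2d(mesh2d, protocol):
    """Simulated frames for lung radii 0.3..0.6 (heart fixed at 0.3)."""
    frames = {}
    for r in (0.3, 0.4, 0.5, 0.6):
        sigma = assign_phantom(mesh2d, PhantomSpec(lung_radius=r))
        frames[r] = solve_forward(mesh2d, sigma, protocol)
    return frames


@pytest.fixture(scope="session")
def frame6_2d(phantom_frames2d):
    """The maximal-expansion (lungs 0.6) frame, the headline scenario."""
    return phantom_frames2d[0.6]
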