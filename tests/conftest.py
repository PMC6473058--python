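"""Shared fixtures: desk-scale phantoms, lead fields, and solved systems.

Everything heavy is session-scoped and generated programmatically; no stored
binary fixtures.  Mesh resolutions and grid sizes here are the package's
documented desk-scale study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

import ctdcsim as c
from ctdcsim.fem import FemSystem, TissueModel
from ctdcsim.leadfield import assemble_leadfield
from ctdcsim.roi import VoxelSampler

HOMOG_RADIUS = 92.0
HOMOG_SIGMA = 0.465
TARGET_LOBULES = ["Right_VIIb", "Right_VIIIa", "Right_VIIIb", "Right_IX"]
CAP_AXIS = np.array([0.0, -1.0, -1.0]) / np.sqrt(2.0)


@pytest.fixture(scope="session")
def homog_shells():
    return [c.ShellSpec("scalp", HOMOG_RADIUS, HOMOG_SIGMA)]


@pytest.fixture(scope="session")
def sphere_mesh(homog_shells):
    """Homogeneous sphere at the default 8 mm resolution."""
    return c.build_shell_phantom(homog_shells, resolution=8.0, seed=1)


@pytest.fixture(scope="session")
def sphere_system(sphere_mesh, homog_shells):
    return FemSystem(sphere_mesh, TissueModel.from_shells(homog_shells))


@pytest.fixture(scope="session")
def head_mesh():
    """Five-shell phantom with the default conductivities."""
    return c.build_shell_phantom(c.DEFAULT_SHELLS, resolution=8.0, seed=1)


@pytest.fixture(scope="session")
def tissues():
    return TissueModel.from_shells(c.DEFAULT_SHELLS)


@pytest.fixture(scope="session")
def head_system(head_mesh, tissues):
    return FemSystem(head_mesh, tissues)


@pytest.fixture(scope="session")
def parc(head_mesh):
    """2 mm parcellation grid (desk-scale; the library default is 1 mm)."""
    return c.build_parcellation(head_mesh, voxel_size=2.0)


@pytest.fixture(scope="session")
def sampler(head_mesh, parc):
    return VoxelSampler(head_mesh, parc.affine, parc.shape)


@pytest.fixture(scope="session")
def catalog8():
    return c.candidate_layout("quasi-uniform", n=8, reference_id="Cz", scalp_radius=HOMOG_RADIUS)


@pytest.fixture(scope="session")
def lf8(head_mesh, tissues, catalog8, parc, head_system, sampler):
    return assemble_leadfield(
        head_mesh, tissues, catalog8, "Cz", parc, system=head_system, sampler=sampler
    )


@pytest.fixture(scope="session")
def catalog48():
    """Dense candidate catalog for targeting studies (the real workflow uses
    hundreds of scalp positions)."""
    return c.candidate_layout("quasi-uniform", n=48, reference_id="Cz", scalp_radius=HOMOG_RADIUS)


@pytest.fixture(scope="session")
def lf48(head_mesh, tissues, catalog48, parc, head_system, sampler):
    return assemble_leadfield(
        head_mesh, tissues, catalog48, "Cz", parc, system=head_system, sampler=sampler
    )
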