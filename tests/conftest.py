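"""Shared fixtures: all test geometry is generated, never loaded from disk."""

import numpy as np
import pytest
import trimesh

from tubeprint.synthetic import ColonSpec, make_colon_mesh

# a shorter, coarser folded tube for the heavier pipeline tests
SMALL_COLON_SPEC = ColonSpec(
    control_points=((0.0, 0.0, 0.0), (50.0, 20.0, 8.0), (100.0, -8.0, 25.0),
                    (150.0, 22.0, 38.0)),
    base_radius=14.0, fold_cycles=5.0, n_axial=120, n_theta=32)


@pytest.fixture(scope="session")
def colon():
    mesh, gt = make_colon_mesh()
    return mesh, gt


@pytest.fixture(scope="session")
def small_colon():
    mesh, gt = make_colon_mesh(SMALL_COLON_SPEC)
    return mesh, gt


@pytest.fixture(scope="session")
def unit_cube():
    box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    return box


@pytest.fixture(scope="session")
def sphere10():
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


@pytest.fixture(scope="session")
def straight_tube():
    spec = ColonSpec(control_points=((0, 0, 0), (100.0, 0, 0)),
                     fold_amplitude=0.0, radius_taper=0.0, base_radius=10.0,
                     n_axial=80, n_theta=48)
    mesh, gt = make_colon_mesh(spec)
    return mesh, gt


@pytest.fixture(scope="session")
def elliptic_tube():
    cyl = trimesh.creation.cylinder(radius=1.0, height=50.0, sections=96)
    return trimesh.Trimesh(vertices=cyl.vertices * np.array([10.0, 5.0, 1.0]),
                           faces=cyl.faces, process=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
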