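"""Shared fixtures: meshes and operators reused across the suite."""

import numpy as np
import pytest

from nasospray import geometry as geo
from nasospray.film import SurfaceOperators


@pytest.fixture(scope="session")
def nose_mesh():
    """Default-resolution synthetic nasal passage (the study geometry)."""
    return geo.build_idealized_nasal_passage()


@pytest.fixture(scope="session")
def nose_ops(nose_mesh):
    return SurfaceOperators(nose_mesh)


@pytest.fixture(scope="session")
def coarse_mesh():
    """Coarser passage for fast pipeline-level tests."""
    params = geo.NasalGeometryParams(target_edge_length=2.5e-3)
    return geo.build_idealized_nasal_passage(params)


@pytest.fixture(scope="session")
def coarse_ops(coarse_mesh):
    return SurfaceOperators(coarse_mesh)


@pytest.fixture(scope="session")
def flat_patch():
    return geo.flat_patch_mesh(nx=16, ny=16, lx=1.0, ly=1.0)


@pytest.fixture(scope="session")
def flat_patch_ops(flat_patch):
    return SurfaceOperators(flat_patch)
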