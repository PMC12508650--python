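import numpy as np
import pytest

from braingrid.grid import BrainGrid, PlaneSet, TemplateGeometry, build_grid


@pytest.fixture(scope="session")
def toy_geometry() -> TemplateGeometry:
    """Small 4 mm lattice centred on the origin (shape 24x28x24)."""
    affine = np.array(
        [
            [-4.0, 0.0, 0.0, 46.0],
            [0.0, 4.0, 0.0, -56.0],
            [0.0, 0.0, 4.0, -46.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return TemplateGeometry((24, 28, 24), affine)


@pytest.fixture(scope="session")
def toy_planes() -> PlaneSet:
    return PlaneSet(axial_mm=(-20.0, 2.0, 26.0), coronal_mm=(-30.0, 8.0), sagittal_mm=(-22.0, 0.0, 22.0))


@pytest.fixture(scope="session")
def toy_grid(toy_planes, toy_geometry) -> BrainGrid:
    return build_grid(toy_planes, toy_geometry)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
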