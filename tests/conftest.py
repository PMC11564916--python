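"""Shared fixtures: a seeded reference case and sampled fractions.

Heavy phantom objects are session-scoped so the whole suite generates them
once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ddacc.grids import GridSpec, ScalarVolume, StructureMask
from ddacc.phantom import PhantomParams, generate_reference_case, sample_fraction_anatomy


@pytest.fixture(scope="session")
def default_params() -> PhantomParams:
    return PhantomParams(seed=1)


@pytest.fixture(scope="session")
def ref_case(default_params):
    """Patient 1 reference case of the seeded default cohort."""
    return generate_reference_case(default_params, 1)


@pytest.fixture(scope="session")
def fraction10(ref_case, default_params):
    """A mid-treatment fraction with shift, filling change and wall push."""
    return sample_fraction_anatomy(ref_case, 10, default_params)


@pytest.fixture()
def small_grid() -> GridSpec:
    return GridSpec(shape=(12, 10, 8), spacing=(2.0, 2.0, 2.0), origin=(-10.0, -9.0, -7.0))


def make_volume(grid: GridSpec, fn) -> ScalarVolume:
    """Scalar volume from a function of world coordinates."""
    centers = grid.voxel_centers_world()
    return ScalarVolume(grid, np.asarray(fn(centers), dtype=np.float64))


def make_sphere_mask(grid: GridSpec, center, radius, label="CTV") -> StructureMask:
    centers = grid.voxel_centers_world()
    d2 = ((centers - np.asarray(center, dtype=float)) ** 2).sum(axis=-1)
    return StructureMask(grid, d2 <= radius**2, label)
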