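"""Shared fixtures: small synthetic imaging configurations.

The expensive full-scale (4096 px, 100 um sphere) configuration lives in
the acceptance tests only; unit tests run on scaled-down spheres whose
fringe structure is still rich enough to exercise every code path.
"""

from __future__ import annotations

import numpy as np
import pytest

from holocri.ftls import scattering_curve
from holocri.materials import pmma_index
from holocri.retrieval import retrieve_field
from holocri.synthesize import make_hologram, synthesize_field, uniform_field
from holocri.types import ComplexIndex, ImageGrid, SphereSpec


@pytest.fixture(scope="session")
def small_grid() -> ImageGrid:
    return ImageGrid(512, 0.2, 0.25)


@pytest.fixture(scope="session")
def mid_grid() -> ImageGrid:
    return ImageGrid(1024, 0.2, 0.25)


@pytest.fixture(scope="session")
def medium() -> ComplexIndex:
    return ComplexIndex(1.3518, 1e-4)


@pytest.fixture(scope="session")
def mid_sphere() -> SphereSpec:
    return SphereSpec(20.0, pmma_index)


@pytest.fixture(scope="session")
def mid_chain(mid_grid, mid_sphere, medium):
    """Noise-free synthetic chain at 20 um / 1024 px, 500 nm.

    Returns (field, sample hologram, background hologram, retrieved field,
    scattering curve); session-scoped because several modules reuse it.
    """
    wl = 500.0
    fld = synthesize_field(mid_sphere, medium, wl, mid_grid)
    sample = make_hologram(fld)
    background = make_hologram(
        uniform_field(medium, wl, mid_grid, mid_sphere.diameter_um))
    retrieved = retrieve_field(sample, background)
    curve = scattering_curve(retrieved, medium.n, n_bins=100)
    return {
        "wavelength_nm": wl,
        "field": fld,
        "sample": sample,
        "background": background,
        "retrieved": retrieved,
        "curve": curve,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
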