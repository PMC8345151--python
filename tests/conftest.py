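"""Shared fixtures: small deterministic phantoms and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from pdxrad.phantom import PhantomSpec, RaterModel, generate_volume


@pytest.fixture(scope="session")
def default_phantom():
    """One full-size default phantom volume with ground truth."""
    spec = PhantomSpec(seed=42)
    vol, gt = generate_volume(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def small_phantom():
    """A small, quick phantom for I/O and radiomics tests."""
    spec = PhantomSpec(
        grid_shape=(8, 48, 48),
        tumor_radii=(2.5, 3.0, 3.0),
        boundary_lumpiness=0.1,
        noise_sigma=6.0,
        seed=7,
    )
    vol, gt = generate_volume(spec)
    return spec, vol, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
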