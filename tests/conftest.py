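"""Shared fixtures: small seeded phantoms reused across the suite."""

import numpy as np
import pytest

from spinemorph.phantom import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom with all five spine classes, default acquisition geometry."""
    spec = PhantomSpec(rng_seed=1)
    stack, seg, gt = build_phantom(spec)
    return spec, stack, seg, gt


@pytest.fixture(scope="session")
def clean_geometry_phantom():
    """Synapse-free phantom: symmetric structures, used for registration
    oracles where oblique presynaptic geometry would make the NCC optimum
    genuinely ambiguous."""
    spec = PhantomSpec(rng_seed=7, nonsynaptic_fraction=1.0, noise_sd=0.0,
                       intensity_drift=0.0, slice_jitter_px=3,
                       n_spines_per_type={"thin": 1, "mushroom": 1, "stubby": 1})
    stack, seg, gt = build_phantom(spec)
    return spec, stack, seg, gt


def ball_mask(radius_vox: int, pad: int = 2) -> np.ndarray:
    """Digitized ball on an isotropic voxel grid (centers inside the sphere)."""
    n = 2 * (radius_vox + pad) + 1
    c = radius_vox + pad
    z, y, x = np.ogrid[:n, :n, :n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox ** 2
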