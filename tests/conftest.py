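"""Shared fixtures: small phantoms and chest-wall specs built at test time."""

import numpy as np
import pytest

from bpequant import ChestWallSpec, PhantomParams, generate_phantom
from bpequant.phantom import chest_wall_plane_y


def chest_spec_for(params: PhantomParams, n_points: int = 12, seed: int = 0) -> ChestWallSpec:
    """Control points sampled on the phantom's true (planar) chest wall."""
    y_wall = chest_wall_plane_y(params)
    rng = np.random.default_rng(seed)
    nx, ny, nz = params.grid_shape
    sx, sy, sz = params.spacing
    pts = np.column_stack(
        [
            rng.uniform(0, nx * sx, n_points),
            np.full(n_points, y_wall),
            rng.uniform(0, nz * sz, n_points),
        ]
    )
    return ChestWallSpec(control_points=pts)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free, motion-free phantom (exact tissue classes)."""
    params = PhantomParams(seed=11, fgt_fraction=0.10, enhancing_fraction=0.4)
    pre, post, truth = generate_phantom(params)
    return params, pre, post, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom at the stated validation conditions: noise 0.05, bias 0.3, 2 mm motion."""
    params = PhantomParams(
        seed=7,
        spacing=(1.0, 1.0, 1.0),
        fgt_fraction=0.10,
        enhancing_fraction=0.3,
        bias_amplitude=0.3,
        motion_translation=(2.0, 0.0, 0.0),
        noise_sigma=0.05,
    )
    pre, post, truth = generate_phantom(params)
    return params, pre, post, truth
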