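from dataclasses import replace

import numpy as np
import pytest

import vertfe as vf

# Reduced phantoms for solver-heavy tests: geometry scaled down from the
# adult-lumbar default so full failure runs stay cheap on one CPU.
SMALL_SPEC = replace(vf.DEFAULT_SPEC, body_half_axes=(12.0, 9.0), body_height=18.0)
TINY_SPEC = replace(vf.DEFAULT_SPEC, body_half_axes=(9.0, 7.0), body_height=12.0)


@pytest.fixture(scope="session")
def default_phantom():
    return vf.generate_vertebra_phantom(replace(vf.DEFAULT_SPEC, seed=5))


@pytest.fixture(scope="session")
def small_phantom():
    return vf.generate_vertebra_phantom(replace(SMALL_SPEC, seed=3))


@pytest.fixture(scope="session")
def tiny_phantom():
    return vf.generate_vertebra_phantom(replace(TINY_SPEC, seed=3))


def cube_phantom(n_vox=(3, 3, 3), hu=200.0, pad=0):
    """Cuboid of constant HU, optionally padded with background."""
    shape = tuple(n + 2 * pad for n in n_vox)
    labels = np.zeros(shape, dtype=np.uint8)
    core = tuple(slice(pad, pad + n) for n in n_vox)
    labels[core] = 1
    values = np.full(shape, -80.0)
    values[core] = hu
    img = vf.ImageVolume(values, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    mask = vf.LabelMask(labels, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    return img, mask
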