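import numpy as np
import pytest

from leafvol.synthesis import LeafShapeParams, LeafSpecimen


def make_shape(**kw) -> LeafShapeParams:
    defaults = dict(
        length_mm=150.0, max_width_mm=10.0,
        thickness_base_mm=0.30, thickness_middle_mm=0.25, thickness_tip_mm=0.20,
        midrib_base_mm=0.80, midrib_middle_mm=0.60, midrib_tip_mm=0.40,
    )
    defaults.update(kw)
    return LeafShapeParams(**defaults)


@pytest.fixture
def rectangle_specimen() -> LeafSpecimen:
    """100 x 10 mm constant-width, constant-thickness slab, no taper."""
    shape = make_shape(length_mm=100.0, max_width_mm=10.0,
                       thickness_base_mm=0.25, thickness_middle_mm=0.25,
                       thickness_tip_mm=0.25, width_mode="rectangular")
    return LeafSpecimen(shape=shape, specimen_id="rect")


@pytest.fixture
def triangle_specimen() -> LeafSpecimen:
    shape = make_shape(length_mm=100.0, max_width_mm=10.0,
                       width_mode="triangular")
    return LeafSpecimen(shape=shape, specimen_id="tri")


@pytest.fixture
def lanceolate_specimen() -> LeafSpecimen:
    """Default wheat-like outline, ~1178 mm^2."""
    return LeafSpecimen(shape=make_shape(), specimen_id="lance")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
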