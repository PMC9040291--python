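import numpy as np
import pytest

from perivaq.synth import SceneSpec, VesselSpec, generate_vessel_scene


@pytest.fixture(scope="session")
def capillary_scene():
    """Noiseless 8-um capillary field with a flat (halo-free) surround."""
    spec = SceneSpec(
        width_px=256,
        height_px=256,
        vessels=(VesselSpec((128.0, 128.0), 8.0),),
        endfoot_intensity=200.0,
        pv_astro_intensity=100.0,
        neuropil_intensity=100.0,
        seed=0,
    )
    return spec, *generate_vessel_scene(spec)


@pytest.fixture(scope="session")
def large_vessel_scene():
    """Noiseless 20-um penetrating vessel with the three-step radial scene."""
    spec = SceneSpec(
        width_px=460,
        height_px=460,
        vessels=(VesselSpec((230.0, 230.0), 20.0, kind="disk"),),
        endfoot_intensity=200.0,
        pv_astro_intensity=120.0,
        neuropil_intensity=80.0,
        pv_astro_extent_um=20.0,
        seed=0,
    )
    return spec, *generate_vessel_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
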