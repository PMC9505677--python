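import numpy as np
import pytest

from foulscan import calibrate as cal
from foulscan import simulate as sim
from foulscan.hsio import build_wavelength_grid


@pytest.fixture(scope="session")
def grid63():
    return build_wavelength_grid(420.0, 730.0, 5.0)


@pytest.fixture(scope="session")
def instrument():
    return sim.default_instrument()


@pytest.fixture(scope="session")
def plan(instrument, grid63):
    # expose for the brightest surface (white panel, ~45% reflectance)
    return sim.plan_exposures(instrument, grid63, 0.45, 0.8)


@pytest.fixture(scope="session")
def flat_scene():
    """64x64 panel with two spectrally flat patches, no jitter."""
    ems = {
        "panel_white": sim.generate_endmember("panel_white", seed=0, dip_depth_jitter=0),
        "flat30": sim.EndmemberSpectrum("flat30", np.full(sim.FINE_GRID_NM.shape, 0.30)),
        "flat08": sim.EndmemberSpectrum("flat08", np.full(sim.FINE_GRID_NM.shape, 0.08)),
    }
    layout = [
        sim.ShapeSpec("rectangle", "flat30", (32, 16), (40, 20)),
        sim.ShapeSpec("rectangle", "flat08", (32, 48), (40, 20)),
    ]
    return sim.generate_scene(layout, ems, (64, 64), "panel_white", seed=1, brightness_jitter=0.0)


def acquire_triple(scene, instrument, plan, noise=False, seeds=(0, 1, 2), r_ref=0.10):
    raw = sim.simulate_raw_cube(scene, instrument, plan, "scene", r_ref, noise, seeds[0])
    bright = sim.simulate_raw_cube(scene, instrument, plan, "reference", r_ref, noise, seeds[1])
    dark = sim.simulate_raw_cube(scene, instrument, plan, "dark", r_ref, noise, seeds[2])
    return cal.CalibrationSet(raw, bright, dark, r_ref, instrument.saturation_ceiling)


@pytest.fixture(scope="session")
def flat_calset(flat_scene, instrument, plan):
    return acquire_triple(flat_scene, instrument, plan, noise=False)


@pytest.fixture(scope="session")
def flat_reflectance(flat_calset):
    return cal.reflectance_transform(flat_calset)
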