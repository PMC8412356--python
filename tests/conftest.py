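import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from scpnscreen.segment import FieldImage  # noqa: E402
from scpnscreen.simulate import (NULL_EFFECT, default_screen_scenario,  # noqa: E402
                                 generate_field)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_design():
    design, models, effects = default_screen_scenario(
        n_compounds=1, n_enhancers=0, n_toxic=0)
    return design, models, effects


@pytest.fixture(scope="session")
def rendered_field(default_design):
    """One default-density field (truth table, channel images, FieldImage)."""
    design, models, _ = default_design
    rng = np.random.default_rng(5)
    cells, imgs = generate_field(models["untreated"], NULL_EFFECT, design, rng)
    image = FieldImage(channels=imgs, pixel_scale=design.image_spec.pixel_scale,
                       bit_depth=design.image_spec.bit_depth)
    return cells, imgs, image


def make_disk_image(centers_um, radii_um, intensities, shape=(128, 128),
                    scale=0.65, marker_value=None, background=0.0):
    """Hard-edged disks on a constant background (no noise, no anti-aliasing)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    hoechst = np.full(shape, float(background))
    marker = np.full(shape, float(background))
    for (cx, cy), r, v in zip(centers_um, radii_um, intensities):
        disk = ((xx - cx / scale) ** 2 + (yy - cy / scale) ** 2) <= (r / scale) ** 2
        hoechst[disk] = v
        if marker_value is not None:
            marker[disk] = marker_value
    channels = {"hoechst": hoechst}
    if marker_value is not None:
        channels["ch488"] = marker
    return FieldImage(channels=channels, pixel_scale=scale)
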