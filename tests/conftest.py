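import numpy as np
import pytest

from rootfringe import CalibrationConfig, geometry, synthetic, traits


@pytest.fixture(scope="session")
def cal():
    return CalibrationConfig(conv=102.0, resolution=20)


@pytest.fixture(scope="session")
def straight_constant(cal):
    """Small straight root, uniform 30 px fringes; mask + ground truth."""
    spec = synthetic.SyntheticRootSpec(
        image_height=620,
        image_width=260,
        tip_row=590,
        top_row=10,
        root_width=21,
    )
    image, mask, truth = synthetic.generate(spec, conv=cal.conv)
    return spec, image, mask, truth


@pytest.fixture(scope="session")
def straight_constant_scene(straight_constant, cal):
    _, _, mask, _ = straight_constant
    return geometry.normalize(mask, cal)


@pytest.fixture(scope="session")
def ramp_fixture(cal):
    """Straight root with a hair ramp 0 -> 100 px over 500 px, then flat."""
    spec = synthetic.SyntheticRootSpec(
        image_height=1400,
        image_width=400,
        tip_row=1350,
        top_row=10,
        hair_profile_left=synthetic.RampProfile(500, 100),
        hair_profile_right=synthetic.RampProfile(500, 100),
    )
    image, mask, truth = synthetic.generate(spec, conv=cal.conv)
    return spec, image, mask, truth


@pytest.fixture(scope="session")
def ramp_profile_measured(ramp_fixture, cal):
    _, _, mask, _ = ramp_fixture
    scene = geometry.normalize(mask, cal)
    return scene, traits.bin_profile(scene, cal, name="ramp")
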