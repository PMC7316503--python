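import numpy as np
import pytest

from loopscope import (
    ExtruderConfig,
    StrandConfig,
    WLCParams,
    render_kymograph,
    simulate_extrusion,
)


@pytest.fixture(scope="session")
def wlc_default():
    """Community-standard WLC constants with an 18 um dye-corrected contour."""
    return WLCParams(contour_length_um=18.0)


@pytest.fixture()
def strand():
    """Small, fast strand: RE0 = 0.3, 120 frames at 5 Hz."""
    return StrandConfig(end_to_end_um=5.4, contour_length_um=18.0, n_frames=120)


@pytest.fixture()
def one_sided_extruder():
    return ExtruderConfig(
        mode="one_sided_left",
        rate_left_kbps=2.0,
        stall_force_pN=0.5,
        landing_position_kb=0.7 * 48.5,
    )


@pytest.fixture()
def two_sided_extruder():
    return ExtruderConfig(
        mode="two_sided",
        rate_left_kbps=1.0,
        rate_right_kbps=1.0,
        stall_force_pN=0.5,
        landing_position_kb=48.5 / 2,
    )


@pytest.fixture()
def one_sided_truth(strand, one_sided_extruder):
    return simulate_extrusion(strand, one_sided_extruder)


@pytest.fixture()
def two_sided_truth(strand, two_sided_extruder):
    return simulate_extrusion(strand, two_sided_extruder)


@pytest.fixture()
def noiseless_kymo(one_sided_truth):
    return render_kymograph(one_sided_truth, noiseless=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
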