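import numpy as np
import pytest

from spiralpvm.acquisition import AcquisitionParams
from spiralpvm.phantom import build_motion_model, render_velocity_frames


@pytest.fixture(scope="session")
def params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def small_render(params):
    """Mid-slice phantom on a 64-pixel grid (1.4 mm pixels, 90 mm FOV)."""
    model = build_motion_model("mid", seed=5)
    return render_velocity_frames(model, params, grid_size=64)


@pytest.fixture(scope="session")
def small_model(small_render):
    return small_render.ground_truth.model
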