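import numpy as np
import pytest

from granulab.synth import (
    TanksInSeriesSpec,
    TubeImageSpec,
    render_tube_image,
    synthetic_concentration_calibration,
    tanks_in_series_E,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tanks3_images():
    """Zero-noise tube images from a 3-tank truth (t_m = 100 s)."""
    tanks = TanksInSeriesSpec(3, 100.0)
    spec = TubeImageSpec()
    cal = synthetic_concentration_calibration(spec.blank_lstar)
    sample, blank, truth = render_tube_image(
        lambda t: tanks_in_series_E(tanks, t), cal, spec, 0.0, 400.0,
        amplitude=tanks.amplitude)
    return {"sample": sample, "blank": blank, "truth": truth,
            "spec": spec, "tanks": tanks, "cal": cal}
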