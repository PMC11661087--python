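import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from axoncaliber import (
    ImageFrame,
    MeasurementConfig,
    SceneConfig,
    centerline_from_truth,
    make_straight_tube_truth,
    measure_along_segment,
    render_membrane_frame,
)


@pytest.fixture
def scene():
    return SceneConfig(seed=11)


@pytest.fixture
def measure_tube():
    """Render a straight tube of known diameter and measure along it."""

    def _run(diameter, seed=11, poisson=False, positions=None, config=None, angle_deg=0.0):
        sc = SceneConfig(seed=seed, poisson_noise=poisson)
        truth = make_straight_tube_truth(
            diameter=diameter, config=sc, length=10.0, angle_deg=angle_deg
        )
        img = render_membrane_frame(truth, sc)
        frame = ImageFrame(img, pixel_size=sc.pixel_size)
        cl = centerline_from_truth(truth)
        if positions is None:
            positions = np.arange(1.0, 9.5)
        return measure_along_segment(frame, cl, 0, positions, config or MeasurementConfig())

    return _run
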