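import numpy as np
import pytest

from crowdbench.stimuli import StimulusGeometry


@pytest.fixture(scope="session")
def small_geometry() -> StimulusGeometry:
    """Compact frame for fast unit tests; still fits 8 flankers per side."""
    return StimulusGeometry(
        image_width_px=256, image_height_px=256,
        vernier_height=32.0, vernier_offset=2.0, vernier_gap=4.0,
        line_width=2.0, element_spacing=12.0,
    )


@pytest.fixture(scope="session")
def default_geometry() -> StimulusGeometry:
    return StimulusGeometry(eccentricity_deg=3.88)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240914)
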