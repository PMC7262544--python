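import numpy as np
import pytest
from hypothesis import settings

from metalloscreen import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def single_colony_plate():
    """Noiseless 100x100 plate with one colony (r=10) and halo (outer r=15)."""
    spec = synthetic.PlateSpec(
        image_height=100,
        image_width=100,
        colonies=(synthetic.ColonySpec(center_row=50, center_col=50,
                                       colony_radius=10, halo_outer_radius=15),),
    )
    image, truth = synthetic.generate_plate(spec)
    return spec, image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
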