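import numpy as np
import pytest
from hypothesis import settings

import ammoflow as af

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    return af.default_frame_schedule()


@pytest.fixture(scope="session")
def grid():
    return af.uniform_grid(3.0)


@pytest.fixture(scope="session")
def input_curves(grid):
    """Default bolus-shaped LV/RV input curves on the 3-min fine grid."""
    return af.generate_input_function(af.InputFunctionParams(), grid)


@pytest.fixture(scope="session")
def uniform_subject():
    """Noiseless subject with identical kinetics in every segment."""
    truth = af.SubjectTruth(
        k1_stress=np.full(17, 2.4),
        k1_rest=np.full(17, 0.9),
        noise_level=0.0,
        seed=11,
    )
    stress, rest = af.simulate_subject(truth)
    return truth, stress, rest
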