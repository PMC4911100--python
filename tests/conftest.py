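import numpy as np
import pytest

from boldnvc import (SyntheticSpec, generate_group_bold, make_model,
                     reference_parameter_set, single_trial,
                     study_intensity_truth)


@pytest.fixture(scope="session")
def grid():
    """Acquisition grid: TR = 0.5 s over the -1 to 17.5 s trial window."""
    return np.arange(-1.0, 17.51, 0.5)


@pytest.fixture(scope="session")
def fine_grid():
    return np.arange(-1.0, 17.51, 0.25)


@pytest.fixture(scope="session")
def trial():
    return single_trial()


@pytest.fixture(scope="session")
def mn2():
    return make_model("Mn2")


@pytest.fixture(scope="session")
def mm2():
    return make_model("Mm2")


@pytest.fixture(scope="session")
def mnm2():
    return make_model("Mnm2")


@pytest.fixture(scope="session")
def mn2_truth():
    return reference_parameter_set("Mn2_canonical")


@pytest.fixture(scope="session")
def intensity_standin():
    """Synthetic stand-in for the intensity-experiment estimation series."""
    spec = SyntheticSpec(ground_truth=study_intensity_truth(), seed=42)
    data, subjects = generate_group_bold(spec)
    return data


@pytest.fixture(scope="session")
def mn2_synthetic(mn2, mn2_truth):
    """Group-mean data generated from the minimized feed-forward model."""
    spec = SyntheticSpec(ground_truth=(mn2, mn2_truth), seed=100)
    data, _ = generate_group_bold(spec)
    return data
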