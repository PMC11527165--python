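import numpy as np
import pytest

from insightnet.task import CurriculumSpec, InputModel, build_curriculum, sample_inputs

#: Motion means of realistic magnitude for the default input noise; used
#: wherever a test needs trained networks without paying for matching.
TEST_MEANS = {5: 0.02, 10: 0.03, 20: 0.06, 30: 0.09, 45: 0.13}


@pytest.fixture(scope="session")
def spec():
    return CurriculumSpec()


@pytest.fixture(scope="session")
def input_model():
    return InputModel(M_m=dict(TEST_MEANS))


@pytest.fixture(scope="session")
def curriculum(spec):
    return build_curriculum(spec, rng=np.random.default_rng(123))


@pytest.fixture(scope="session")
def trials(curriculum, input_model):
    return sample_inputs(curriculum, input_model, rng=np.random.default_rng(456))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_series(values, y_min=0.6, onset_bin=4.0, bin_size=50):
    from insightnet.switchfit import AccuracySeries

    return AccuracySeries(
        values=np.asarray(values, dtype=float),
        y_min=y_min,
        onset_bin=onset_bin,
        bin_size=bin_size,
    )
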