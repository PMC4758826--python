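import numpy as np
import pytest

from lfconn.task_design import build_study_design


@pytest.fixture(scope="session")
def instruction_design():
    """Event trains + stage partition for a 2-block instruction session."""
    return build_study_design("instruction", n_blocks=2, seed=11)


@pytest.fixture(scope="session")
def feedback_design():
    """Event trains + stage partition for a 2-block feedback session."""
    return build_study_design("feedback", n_blocks=2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
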