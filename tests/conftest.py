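import numpy as np
import pytest

from asdvoice import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small separable cohort shared by structural tests (delta=3)."""
    cfg = SyntheticCohortConfig(
        n_asd_subjects=4, n_td_subjects=4, utterances_per_subject=(4, 6),
        frames_per_utterance=(12, 25), delta=3.0, seed=123)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
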