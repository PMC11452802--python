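from pathlib import Path

import numpy as np
import pytest

from ticscreen import SimulationConfig, TicProbabilitySeries, generate_cohort

DATA_DIR = Path(__file__).parent / "data"


def make_series(probs, video_id="v", participant_id="p", group="GTS", hidden=None):
    return TicProbabilitySeries(
        video_id=video_id,
        participant_id=participant_id,
        group=group,
        probabilities=np.asarray(probs, dtype=float),
        hidden_states=hidden,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """8-pair cohort with the default (well-separated) group parameters."""
    return generate_cohort(SimulationConfig(n_pairs=8, seed=42))


@pytest.fixture(scope="session")
def full_cohort():
    """Study-sized cohort: 42 matched pairs, 1-4 videos each, 150-s videos."""
    return generate_cohort(SimulationConfig(seed=7))
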