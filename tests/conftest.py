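import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import taxograsp as tg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grasp_set():
    return tg.default_grasp_set(4)


@pytest.fixture(scope="session")
def quick_synth_config(small_grasp_set):
    """Small, fast generator configuration for structural tests."""
    return tg.SynthConfig(
        n_subjects=2, grasp_set=small_grasp_set, n_repetitions=2,
        movement_s=1.0, rest_s=0.5, seed=11,
    )


@pytest.fixture(scope="session")
def quick_recording(quick_synth_config):
    return tg.generate_recording(quick_synth_config, 0)


@pytest.fixture(scope="session")
def quick_windows(quick_recording, small_grasp_set):
    sync = tg.synchronize(quick_recording)
    return tg.segment_windows(sync, grasp_set=small_grasp_set)
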