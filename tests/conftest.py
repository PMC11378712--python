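import numpy as np
import pytest

from rtseq import (
    DesignSpec,
    FilterConfig,
    code_sequence,
    default_ground_truth,
    filter_trials,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def vs_dataset():
    """Small visual-search dataset with known ground truth: 4 participants,
    reduced block design (4 x 42 trials) for test speed."""
    spec = DesignSpec("visual_search", n_blocks=4, trials_per_block=42, n_practice=12)
    truth = default_ground_truth("visual_search", seed=11)
    table, truth = simulate_dataset(spec, truth, n_participants=4, seed=11)
    return table, truth


@pytest.fixture(scope="session")
def vs_coded_filtered(vs_dataset):
    table, truth = vs_dataset
    coded = code_sequence(table)
    filt, _ = filter_trials(coded, FilterConfig(lower_rt_ms=300.0))
    return filt, truth


@pytest.fixture(scope="session")
def ts_dataset():
    """Task-switching dataset (every trial has a defined sequence label),
    6 participants, reduced design."""
    spec = DesignSpec("task_switching", n_blocks=4, trials_per_block=42, n_practice=12)
    truth = default_ground_truth("task_switching", seed=7)
    table, truth = simulate_dataset(spec, truth, n_participants=6, seed=7)
    return table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
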