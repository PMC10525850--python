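"""Shared fixtures.

Heavy experiment fixtures (full study-scale training runs) live in
test_acceptance.py; here we keep small, fast objects reused across the
unit-test modules.
"""

import numpy as np
import pytest

from emgknee import (
    BpnnTrainConfig,
    DbnTrainConfig,
    FitnessConfig,
    PipelineConfig,
    SwarmConfig,
    SyntheticConfig,
    build_dataset,
    generate_subject,
)


@pytest.fixture(scope="session")
def small_config():
    """A short synthetic subject: 4 cycles (16 s) instead of 20 (80 s)."""
    return SyntheticConfig(n_cycles=4, seed=7)


@pytest.fixture(scope="session")
def small_recording(small_config):
    return generate_subject(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_recording):
    cfg = small_recording.config
    return build_dataset(
        small_recording.emg, small_recording.angle, cfg.fs_emg, cfg.fs_angle
    )


@pytest.fixture(scope="session")
def default_recording():
    """One subject at the full study conditions (20 cycles, 80 s)."""
    return generate_subject(SyntheticConfig(seed=7))


@pytest.fixture()
def tiny_pipeline_config():
    """Reduced training budgets for structural/contract tests."""
    return PipelineConfig(
        dbn=DbnTrainConfig(epochs=10, fine_tune_epochs=50),
        bpnn=BpnnTrainConfig(max_iter=150),
        swarm=SwarmConfig(n_particles=4, max_iter=2, pos_max=20),
        fitness=FitnessConfig(dbn_epochs=3, fine_tune_epochs=10, bpnn_max_iter=50),
    )
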