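"""Shared fixtures: toy response matrices and small simulated experiments."""

from __future__ import annotations

import numpy as np
import pytest

from wordia.datasets import hand_worked_toy, make_matrix, random_matrices
from wordia.ia import ResponseMatrix
from wordia.synthetic import SimulationConfig, simulate_experiment

# re-exported for direct import in test modules
random_dataset = random_matrices


@pytest.fixture
def toy_three_images() -> dict[str, ResponseMatrix]:
    """The hand-worked 3-image dataset with word IA exactly 0.625."""
    return hand_worked_toy()


@pytest.fixture(scope="session")
def small_sim():
    """A 20-image simulated experiment shared across tests (seed 7)."""
    cfg = SimulationConfig(n_images=20, trials_per_participant=10, seed=7)
    exp, truth, freq = simulate_experiment(cfg)
    return cfg, exp, truth, freq
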