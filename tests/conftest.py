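"""Shared fixtures.

The trained-policy fixtures are session-scoped because REINFORCE
training, while fast, dominates the suite's runtime; several tests
inspect different aspects of the same training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import fluxrl as fx

TRAIN_SEED = 1
# reduced training budget used throughout the suite (the reference
# setups run 350-500 epochs x 500 episodes; see docs/methods.md)
EPOCHS = 150
EPISODES = 200


@pytest.fixture(scope="session")
def fa_model():
    return fx.fatty_acid_model()


@pytest.fixture(scope="session")
def lac_model():
    return fx.lactate_model()


@pytest.fixture(scope="session")
def fa_grid():
    return fx.ControlGrid(t_end=25.0, n_intervals=25)


@pytest.fixture(scope="session")
def lac_grid():
    return fx.ControlGrid(t_end=9.5, n_intervals=11)


@pytest.fixture(scope="session")
def titer_objective():
    return fx.ObjectiveSpec("terminal_titer")


@pytest.fixture(scope="session")
def golden_batch(lac_model, lac_grid):
    reference, switch = fx.build_golden_batch_reference(lac_model, lac_grid)
    return reference, switch


@pytest.fixture(scope="session")
def fa_training_det(fa_model, fa_grid, titer_objective):
    """Fatty-acid terminal-titer training in the deterministic environment."""
    cfg = fx.TrainingConfig(
        learning_rate=0.0075, epochs=EPOCHS, episodes_per_epoch=EPISODES, seed=TRAIN_SEED
    )
    return fx.train(fa_model, fa_grid, fx.RandomizationSpec(0.0), titer_objective, cfg)


@pytest.fixture(scope="session")
def fa_training_randomized(fa_model, fa_grid, titer_objective):
    """Fatty-acid training under 25% domain randomization."""
    cfg = fx.TrainingConfig(
        learning_rate=0.0075, epochs=EPOCHS, episodes_per_epoch=EPISODES, seed=TRAIN_SEED
    )
    return fx.train(fa_model, fa_grid, fx.RandomizationSpec(0.25), titer_objective, cfg)


@pytest.fixture(scope="session")
def lac_training_det(lac_model, lac_grid, golden_batch):
    """Lactate golden-batch tracking training, deterministic environment."""
    reference, _ = golden_batch
    objective = fx.ObjectiveSpec("reference_tracking", reference=reference)
    cfg = fx.TrainingConfig(
        learning_rate=0.001, epochs=EPOCHS, episodes_per_epoch=EPISODES, seed=TRAIN_SEED
    )
    return fx.train(lac_model, lac_grid, fx.RandomizationSpec(0.0), objective, cfg)
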