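"""Shared fixtures: toy oracles, the seed dataset, and trained committees.

Everything is generated programmatically at session scope so the expensive
pieces (ensemble training) run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from uddal import (
    Configuration,
    Dataset,
    DoubleWellBond,
    LabeledSample,
    MuellerBrown,
    TrainingConfig,
    generate_initial_dataset,
    train_ensemble,
)


@pytest.fixture(scope="session")
def mb() -> MuellerBrown:
    return MuellerBrown()  # default ×0.1 rescaling


@pytest.fixture(scope="session")
def dw() -> DoubleWellBond:
    return DoubleWellBond()


@pytest.fixture(scope="session")
def mb_initial_dataset(mb) -> Dataset:
    """The standard seeding protocol: 5 ps at 350 K, 0.5-fs steps, every 80th."""
    return generate_initial_dataset(
        mb,
        mb.default_seed_configuration(),
        temperature=350.0,
        dt=0.5,
        n_steps=10_000,
        stride=80,
        seed=42,
    )


@pytest.fixture(scope="session")
def mb_ensemble(mb_initial_dataset):
    """The 8-member committee trained on the 125-sample seed set."""
    return train_ensemble(
        mb_initial_dataset, TrainingConfig(seed=7), n_members=8
    )


@pytest.fixture(scope="session")
def small_mb_ensemble(mb_initial_dataset):
    """A cheap 4-member committee for structural/gradient tests."""
    return train_ensemble(
        mb_initial_dataset,
        TrainingConfig(seed=11, max_epochs=120),
        n_members=4,
        hidden_sizes=(16, 8),
    )


@pytest.fixture(scope="session")
def dw_dataset(dw) -> Dataset:
    """Near-minimum seed set for the proton-transfer toy."""
    return generate_initial_dataset(
        dw,
        dw.default_seed_configuration(),
        temperature=300.0,
        dt=0.5,
        n_steps=4_000,
        stride=40,
        seed=13,
    )


@pytest.fixture(scope="session")
def dw_ensemble(dw_dataset):
    return train_ensemble(
        dw_dataset,
        TrainingConfig(seed=17, max_epochs=120),
        n_members=4,
        hidden_sizes=(16, 8),
    )


@pytest.fixture
def single_atom() -> Configuration:
    return Configuration(species=["X"], positions=np.zeros((1, 3)))


def make_labeled(positions_2d, energy, force_2d) -> LabeledSample:
    pos = np.zeros((1, 3))
    pos[0, :2] = positions_2d
    f = np.zeros((1, 3))
    f[0, :2] = force_2d
    return LabeledSample(
        Configuration(species=["X"], positions=pos), energy=energy, forces=f
    )
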