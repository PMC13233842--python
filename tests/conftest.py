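"""Shared fixtures: analytic model systems and desk-scale trained models.

Training fixtures are session-scoped because gradient-descent fits are the
expensive part of the suite; every test that needs a trained model shares
these. All seeds are fixed, so the suite is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from photopot import model_systems as ms
from photopot.descriptor import AEVConfig
from photopot.potential import OscillatorStrengthModel
from photopot.training import TrainConfig, train_ensemble, train_model


@pytest.fixture(scope="session")
def desk_aev() -> AEVConfig:
    return AEVConfig.desk()


@pytest.fixture(scope="session")
def osc3_pes() -> ms.DiatomicPES:
    """Three-state displaced-oscillator manifold on an N2-like diatomic."""
    return ms.DiatomicPES(ms.multistate_oscillator(3))


@pytest.fixture(scope="session")
def osc3_data(osc3_pes):
    return ms.make_synthetic_dataset(osc3_pes, n_geometries=300, seed=0)


@pytest.fixture(scope="session")
def osc3_model(osc3_pes, osc3_data, desk_aev):
    """Accurately trained single 3-state model (test MAE < 0.05 eV per state)."""
    records, registry = osc3_data
    cfg = TrainConfig(
        descriptor=desk_aev,
        hidden_layers=(48, 48),
        n_states_max=3,
        max_epochs=2000,
        learning_rate=1e-2,
        patience=400,
        seed=0,
    )
    return train_model(records, registry, cfg)


@pytest.fixture(scope="session")
def quick_train_cfg(desk_aev) -> TrainConfig:
    """Cheap config for tests that need a fitted model but not high accuracy."""
    return TrainConfig(
        descriptor=desk_aev,
        hidden_layers=(32, 32),
        n_states_max=3,
        max_epochs=200,
        learning_rate=1e-2,
        patience=80,
        seed=0,
    )


@pytest.fixture(scope="session")
def quick_ensemble(osc3_pes, quick_train_cfg):
    records, registry = ms.make_synthetic_dataset(osc3_pes, n_geometries=150, seed=1)
    return train_ensemble(records, registry, quick_train_cfg)


@pytest.fixture(scope="session")
def f_model(osc3_pes, desk_aev):
    """Oscillator-strength model trained on smooth softplus targets."""
    fgen = ms.softplus_f_generator(2, seed=4)
    records, registry = ms.make_synthetic_dataset(
        osc3_pes, n_geometries=300, f_generator=fgen, seed=0
    )
    model = OscillatorStrengthModel(
        descriptor=desk_aev,
        hidden_layers=(32, 32),
        n_states_max=3,
        max_epochs=800,
        learning_rate=1e-2,
        patience=200,
        seed=0,
    )
    return model.fit(records, registry), fgen


@pytest.fixture(scope="session")
def two_level_model(desk_aev):
    """Model trained on two fidelity levels separated by a constant 0.5 eV."""
    pes = ms.DiatomicPES(
        ms.multistate_oscillator(2, displacements=[0.0, 0.15], offsets=[0.0, 4.0])
    )
    records, registry = ms.make_synthetic_dataset(
        pes, n_geometries=400, level_offsets={"A": 0.0, "B": 0.5}, seed=0
    )
    cfg = TrainConfig(
        descriptor=desk_aev,
        hidden_layers=(64, 64),
        n_states_max=2,
        max_epochs=2000,
        learning_rate=1e-2,
        patience=400,
        seed=0,
    )
    return train_model(records, registry, cfg), pes, registry


@pytest.fixture(scope="session")
def lz_reference():
    """Heavy-particle linear Landau-Zener model; classical oracle in closed form."""
    params = ms.LZModelParams(coupling=0.05, slope=1.0, mass=200.0)
    return params, ms.lz_model(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
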