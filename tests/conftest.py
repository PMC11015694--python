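import numpy as np
import pytest

from erpvar.datatypes import EpochSet, canonical_time_axis
from erpvar.synthetic import (
    ComponentParams,
    GeneratorConfig,
    GroupParams,
    default_config,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(amplitudes, labels=None, correct=None, subject_id="S0001",
                time_axis=None):
    """Build a valid EpochSet from a (trials, 2, samples) array."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    n_trials, _, n_samples = amplitudes.shape
    if time_axis is None:
        dt = 1000.0 / 250.0
        time_axis = -200.0 + dt * np.arange(n_samples)
    if labels is None:
        labels = ["standard"] * n_trials
    if correct is None:
        correct = [True] * n_trials
    epochs = EpochSet(
        subject_id=subject_id,
        time_axis=np.asarray(time_axis, dtype=float),
        amplitudes=amplitudes,
        stimulus_label=np.asarray(labels),
        correct=np.asarray(correct, dtype=bool),
    )
    return epochs


@pytest.fixture
def canonical_grid():
    return canonical_time_axis()


def quiet_group(**overrides):
    """GroupParams with no subject heterogeneity, for deterministic tests."""
    params = dict(
        components={
            "P2": ComponentParams(amplitude=6.0, latency=200.0, width=30.0),
            "P3": ComponentParams(amplitude=8.0, latency=420.0, width=60.0),
        },
        amp_jitter_sd=2.0,
        lat_jitter_sd=20.0,
        right_channel_jitter_scale=1.0,
    )
    params.update(overrides)
    return GroupParams(**params)


def small_config(**overrides) -> GeneratorConfig:
    """A fast config: few subjects/trials, no artifacts or errors."""
    params = dict(
        n_cn=2, n_mci=2,
        n_target_trials=16, n_standard_trials=32,
        groups={"CN": quiet_group(), "MCI": quiet_group()},
        noise_sd=5.0, artifact_rate=0.0, behavioral_error_rate=0.0,
        seed=0,
    )
    params.update(overrides)
    cfg = GeneratorConfig(**params)
    cfg.validate()
    return cfg


@pytest.fixture
def table1_config():
    return default_config(n_cn=4, n_mci=4, seed=11)
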