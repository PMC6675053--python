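"""Shared fixtures: small trained networks reused across test modules."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from seqbcpnn import (
    LearningConfig,
    NetworkParams,
    SequenceSpec,
    TrainingProtocol,
    build_input_series,
    make_orthogonal_patterns,
    train_offline,
)
from seqbcpnn.analysis import gains_for_sequences


def train_sequence_net(
    T_p=100.0, IPI=0.0, tau_z_pre=25.0, tau_z_post=5.0, length=5, H=1,
    epochs=50, target_T_per=100.0, dt=0.5, estimator="ewma",
):
    """Train a single forward sequence and set gains for a uniform dwell."""
    pats = make_orthogonal_patterns(H, length, length)
    seq = SequenceSpec(tuple(range(length)))
    series = build_input_series(
        pats, [seq], TrainingProtocol(T_p=T_p, IPI=IPI, epochs=epochs), dt=1.0)
    conn, _ = train_offline(
        series, LearningConfig(tau_z_pre=tau_z_pre, tau_z_post=tau_z_post),
        estimator=estimator)
    params = NetworkParams(H=H, N=pats.n_units, dt=dt)
    g = gains_for_sequences(conn, pats, [seq], target_T_per, params)
    return conn, replace(params, g_a=g), pats, seq


@pytest.fixture(scope="session")
def fig4_net():
    """Five units, one hypercolumn, asymmetric-trace training."""
    return train_sequence_net()


@pytest.fixture(scope="session")
def noise_baseline_net():
    """The noise-characterization baseline: length 5, H=1, slower post trace."""
    return train_sequence_net(tau_z_post=15.0)
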