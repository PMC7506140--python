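"""Shared fixtures.

The expensive computations (SNAIL sweeps, stochastic landscapes, parameter
ensembles) are session-scoped and shared between the unit tests and the
acceptance tests, at desk-scale problem sizes (see docs/methods.md)."""

from __future__ import annotations

import numpy as np
import pytest

from emt_nfatc.bifurcation import hybrid_interval, sweep
from emt_nfatc.ensemble import EnsembleConfig, phase_frequencies, run_ensemble
from emt_nfatc.params import (
    default_core_parameters,
    default_coupled_parameters,
)
from emt_nfatc.pipeline import landscape_at
from emt_nfatc.topology import core_emt, wildtype_coupled

S_GRID = np.linspace(0.0, 500e3, 126)

#: SNAIL levels (molecules) probed in the stochastic landscape analyses
COUPLED_LANDSCAPE_S = (323e3, 330e3, 380e3)
CORE_LANDSCAPE_S = (230e3, 245e3, 260e3)
#: candidate SNAIL levels for the coupled tristable ({E,H,M}) window
TRISTABLE_CANDIDATES = (312e3, 314e3, 316e3, 318e3)

EM_STEPS = 30_000_000
EM_SEEDS = 4

ENSEMBLE_MODELS = 1500
ENSEMBLE_SEED = 20240917


@pytest.fixture(scope="session")
def coupled_params():
    return default_coupled_parameters()


@pytest.fixture(scope="session")
def core_params():
    return default_core_parameters()


@pytest.fixture(scope="session")
def coupled_diagram(coupled_params):
    return sweep(coupled_params, S_GRID, seed=0)


@pytest.fixture(scope="session")
def core_diagram(core_params):
    return sweep(core_params, S_GRID, seed=0)


@pytest.fixture(scope="session")
def coupled_interval(coupled_diagram, coupled_params):
    return hybrid_interval(coupled_diagram, coupled_params)


@pytest.fixture(scope="session")
def core_interval(core_diagram, core_params):
    return hybrid_interval(core_diagram, core_params)


@pytest.fixture(scope="session")
def sensitivity_result(coupled_params, core_params):
    from emt_nfatc.bifurcation import sensitivity

    return sensitivity(coupled_params, core_params, S_grid=S_GRID, seed=0)


@pytest.fixture(scope="session")
def coupled_landscapes():
    """Mean residence times and barriers at the probed SNAIL levels."""
    out = {}
    for S in COUPLED_LANDSCAPE_S:
        out[S] = landscape_at(default_coupled_parameters(S),
                              em_steps=EM_STEPS, em_seeds=EM_SEEDS, seed=11)
    return out


@pytest.fixture(scope="session")
def core_landscapes():
    out = {}
    for S in CORE_LANDSCAPE_S:
        out[S] = landscape_at(default_core_parameters(S),
                              em_steps=EM_STEPS, em_seeds=EM_SEEDS, seed=13)
    return out


@pytest.fixture(scope="session")
def ensemble_table():
    config = EnsembleConfig(n_models=ENSEMBLE_MODELS, replicates=3,
                            seed=ENSEMBLE_SEED)
    return phase_frequencies([core_emt(), wildtype_coupled()], config)


@pytest.fixture(scope="session")
def coupled_models():
    """One classified coupled-circuit ensemble, reused by the stability
    and classification tests."""
    return run_ensemble(wildtype_coupled(), ENSEMBLE_MODELS, 100,
                        seed=ENSEMBLE_SEED + 5)
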