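"""Shared fixtures: one toy complex and one membrane-preset run.

All synthetic inputs are generated in-process; nothing is read from
disk except in round-trip tests that write their own temp files.
"""

import numpy as np
import pytest

import loxtraj as lx
from loxtraj import synthetic as syn

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def toy():
    """(model, manifest) of the default toy complex."""
    return lx.build_toy_complex(lx.ComplexSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def membrane_run(toy_model):
    """(traj, labels) of the 2000-frame membrane-preset trajectory."""
    dyn = syn.membrane_preset(n_frames=2000, seed=FIXTURE_SEED)
    return lx.simulate_two_state_trajectory(toy_model, dyn)


@pytest.fixture(scope="session")
def recovery_run(toy_model):
    """Membrane-geometry dynamics (Δθ=+20°, σ=2°) on a recurrent
    closed/open chain, so both states are well-sampled for
    state-conditional parameter recovery."""
    dyn = syn.DynamicsSpec(n_frames=2000, theta_closed=90.0,
                           theta_open=110.0, sigma_theta=2.0,
                           p_closed_to_open=0.05, p_open_to_closed=0.05,
                           seed=FIXTURE_SEED)
    return lx.simulate_two_state_trajectory(toy_model, dyn)


@pytest.fixture(scope="session")
def partition(toy_model):
    return lx.DomainPartition(
        beta_barrel=lx.select(toy_model, "chain B"),
        catalytic_domain=lx.select(toy_model, "chain C and not name FE"),
        scaffold=lx.select(toy_model, "chain P"),
        fe=lx.select(toy_model, "name FE"),
        substrate_c13=lx.select(toy_model, "chain S and name C13"),
        substrate_c10=lx.select(toy_model, "chain S and name C10"),
        lipids=lx.select(toy_model, "chain M"))


@pytest.fixture()
def rng():
    return np.random.default_rng(FIXTURE_SEED)
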