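import numpy as np
import pytest

from synchain.fixtures import nonlinear_ref
from synchain.model import DendriticModulation, ModelParams, build_network


@pytest.fixture(scope="session")
def ref():
    """Calibrated nonlinear reference parameters and modulation."""
    return nonlinear_ref()


@pytest.fixture(scope="session")
def small_params():
    """Down-scaled network for fast simulation tests (same physics)."""
    params, _ = nonlinear_ref()
    return params.replace(N=300)


@pytest.fixture(scope="session")
def small_net(small_params):
    return build_network(small_params, seed=1234)


@pytest.fixture(scope="session")
def ref_mod():
    _, mod = nonlinear_ref()
    return mod


@pytest.fixture(scope="session")
def linear_mod():
    return DendriticModulation.identity()


@pytest.fixture(scope="session")
def ref_theory(ref):
    """Diffusion-theory pipeline on the nonlinear reference fixture."""
    from synchain.theory import (
        build_transition_model,
        self_consistent_rate,
        stationary_density_diffusion,
    )

    params, mod = ref
    nu = self_consistent_rate(params, mod)
    dens = stationary_density_diffusion(params, nu, mod)
    model = build_transition_model(params, mod, dens)
    return nu, dens, model
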