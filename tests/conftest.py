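import numpy as np
import pytest

from soltemper import build_ladder
from soltemper.toysim import IntegratorConfig, ToySystem


@pytest.fixture(scope="session")
def cln_ladder():
    """The 10-rung T_ref = 300 K ladder (280–540 K, one cold interval)."""
    return build_ladder(280.0, 540.0, 300.0, 10, n_below_ref=1)


@pytest.fixture(scope="session")
def harmonic_system():
    """10 solute + 10 solvent harmonic coordinates, uncoupled (exact Z)."""
    return ToySystem(d_solute=10, d_solvent=10, k_solute=1.0, k_solvent=1.0)


@pytest.fixture()
def integrator():
    return IntegratorConfig(timestep=0.1, friction=1.0, t_ref=300.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
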