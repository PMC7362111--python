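import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from polyhre.forcefield import ForceField
from polyhre.simulate import build_initial_frame
from polyhre.topology import (
    IonContent,
    ParticleSystem,
    build_chain,
    ions_for_molality,
    solvent_mass_for_box,
)


@pytest.fixture(scope="session")
def small_system():
    """8-monomer PASA-like chain with a little CaCl2, 5 nm box."""
    top = build_chain(8, 1)
    ions = ions_for_molality(0.3, solvent_mass_for_box(5.0),
                             top.total_charge)
    return ParticleSystem(topology=top, ions=ions)


@pytest.fixture(scope="session")
def small_frame(small_system):
    return build_initial_frame(small_system, 5.0,
                               np.random.default_rng(42))


@pytest.fixture(scope="session")
def saltfree_system():
    top = build_chain(6, 1)
    return ParticleSystem(topology=top, ions=IonContent(0, 0, 6))


@pytest.fixture
def default_ff():
    return ForceField()
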