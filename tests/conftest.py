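import numpy as np
import pytest

from colsim.cells import (
    CellTemplate,
    ChannelSpec,
    CompartmentTree,
    GateSpec,
    RateFunction,
    SQUID_K,
    SQUID_NA,
    SynapseSpec,
)
from colsim.fixtures import generate_fixture_set


@pytest.fixture(scope="session")
def fixture_set():
    """One seeded 12-type fixture set shared across the session."""
    return generate_fixture_set(1)


@pytest.fixture
def passive_single():
    """One passive compartment: RC circuit with tau = Rm * Cm."""
    tree = CompartmentTree([-1], 30e-6, 20e-6, 1.0, 1.0, 0.01, -0.065)
    return CellTemplate(
        "passive", 2, True, tree,
        channels=[[]],
        receptors=[[SynapseSpec(0.5e-3, 3e-3, 0.0)]],
        soma=0,
    )


@pytest.fixture
def hh_single():
    """One compartment with the squid Na/K pair (active, spiking)."""
    tree = CompartmentTree([-1], 30e-6, 20e-6, 1.0, 0.3, 0.01, -0.065)
    return CellTemplate(
        "hh", 2, True, tree,
        channels=[[SQUID_NA, SQUID_K]],
        receptors=[[SynapseSpec(0.5e-3, 3e-3, 0.0)]],
        soma=0,
    )


def random_tree(rng: np.random.Generator, n: int) -> CompartmentTree:
    """A random Hines-ordered passive tree with heterogeneous geometry."""
    parent = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
    return CompartmentTree(
        parent=parent,
        length=rng.uniform(20e-6, 150e-6, n),
        diameter=rng.uniform(0.5e-6, 20e-6, n),
        axial_resistivity=float(rng.uniform(0.5, 2.0)),
        membrane_resistivity=float(rng.uniform(0.2, 3.0)),
        membrane_capacitance=0.01,
        leak_reversal=-0.065,
    )


def passive_template(tree: CompartmentTree, name: str = "t") -> CellTemplate:
    n = tree.n_comp
    return CellTemplate(
        name, 2, True, tree,
        channels=[[] for _ in range(n)],
        receptors=[[] for _ in range(n)],
        soma=0,
    )
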