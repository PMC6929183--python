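"""Shared fixtures: reference toy systems and thermodynamic settings."""

import pytest

from isokie.constants import force_constant_nm_to_au
from isokie.synthetic import ToySystemSpec, default_transfer_spec, make_toy_reaction, make_toy_species
from isokie.thermo import ThermoSettings


@pytest.fixture(scope="session")
def th_room():
    return ThermoSettings(temperature=298.15)


@pytest.fixture(scope="session")
def hcl_spec():
    """HCl-like diatomic with the spectroscopic force constant 516 N/m."""
    return ToySystemSpec(
        kind="diatomic",
        labels=("H", "Cl"),
        masses=(1.00782503, 34.96885268),
        distances=(1.2746,),
        bond_k=(force_constant_nm_to_au(516.0),),
    )


@pytest.fixture(scope="session")
def hcl_system(hcl_spec):
    return make_toy_species(hcl_spec)


@pytest.fixture(scope="session")
def transfer_reaction():
    """Reactant/TS pair of the default Cl–C–H···O proton-transfer toy."""
    return make_toy_reaction(default_transfer_spec(with_chlorine=True))


@pytest.fixture(scope="session")
def transfer_reaction_3atom():
    return make_toy_reaction(default_transfer_spec(with_chlorine=False))
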