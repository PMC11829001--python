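import numpy as np
import pytest

from ternadock.scoring import FilterConfig
from ternadock.structure import (
    AtomRecord,
    MoietyTag,
    Structure,
    TernaryInput,
)
from ternadock.synthetic import make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """Default toy ternary complex and its native (identity) pose."""
    return make_toy_complex()


@pytest.fixture(scope="session")
def toy_input(toy):
    return toy[0]


@pytest.fixture(scope="session")
def native_pose(toy):
    return toy[1]


@pytest.fixture
def fast_filters():
    """Filter settings with a coarser SASA sphere for quick tests."""
    return FilterConfig(sasa_points=120)


def atom(serial, name, element, coords, chain="A", resname="ALA", resseq=1,
         hetero=False, mass=None):
    import gemmi

    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        chain_id=chain,
        residue_seq=resseq,
        insertion_code=" ",
        coordinates=np.asarray(coords, dtype=float),
        mass=mass if mass is not None else gemmi.Element(element).weight,
        is_hetero=hetero,
    )


@pytest.fixture
def make_pair_input():
    """Factory for minimal hand-built receptor/mobile inputs."""

    def build(receptor_atoms, mobile_atoms):
        receptor_atoms = list(receptor_atoms)
        mobile_atoms = list(mobile_atoms)
        # one hetero moiety atom per side so the input validates
        receptor_atoms.append(
            atom(400, "C1", "C", [0.0, -8.0, 0.0], chain="A",
                 resname="LIG", resseq=900, hetero=True)
        )
        mobile_atoms.append(
            atom(900, "C1", "C", [4.0, -8.0, 0.0], chain="B",
                 resname="LIG", resseq=900, hetero=True)
        )
        return TernaryInput(
            receptor=Structure(receptor_atoms),
            mobile=Structure(mobile_atoms),
            receptor_moiety=MoietyTag("anchor", frozenset({400})),
            mobile_moiety=MoietyTag("warhead", frozenset({900})),
        )

    return build
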