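import numpy as np
import pytest

from cavgrid import (
    Atom,
    Structure,
    UnitCell,
    detect_pockets,
    make_hollow_shell,
    make_neck_chamber,
    make_tube_crystal,
    run_channels,
)


def make_atom(
    serial=1,
    name="C",
    element="C",
    coords=(0.0, 0.0, 0.0),
    chain_id="A",
    residue_name="DUM",
    residue_number=1,
    **kwargs,
):
    return Atom(
        serial=serial,
        name=name,
        element=element,
        coords=tuple(coords),
        chain_id=chain_id,
        residue_name=residue_name,
        residue_number=residue_number,
        **kwargs,
    )


def structure_from_points(points, **kwargs) -> Structure:
    atoms = [
        make_atom(serial=i + 1, coords=tuple(p), residue_number=i + 1)
        for i, p in enumerate(np.asarray(points, dtype=float))
    ]
    return Structure(atoms, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def hollow_shell_structure():
    return make_hollow_shell(cavity_radius=5.0, shell_thickness=3.0, mouth_radius=2.0)


@pytest.fixture(scope="session")
def hollow_shell_pockets(hollow_shell_structure):
    return detect_pockets(hollow_shell_structure)


@pytest.fixture(scope="session")
def tube_structure():
    return make_tube_crystal(tube_radius=4.0, cell_edge=20.0)


@pytest.fixture(scope="session")
def tube_result(tube_structure):
    return run_channels(tube_structure)


@pytest.fixture(scope="session")
def constricted_tube_result():
    structure = make_tube_crystal(tube_radius=4.0, cell_edge=20.0, constriction_radius=2.0)
    return run_channels(structure)


@pytest.fixture(scope="session")
def neck_chamber_structure():
    return make_neck_chamber(
        chamber_radius=5.0, neck_radius=2.0, channel_radius=5.0, cell_edge=24.0
    )


@pytest.fixture(scope="session")
def neck_chamber_result(neck_chamber_structure):
    return run_channels(neck_chamber_structure, ligand="LIG:L:1")
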