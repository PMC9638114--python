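import numpy as np
import pytest

from parpscreen.energy import ComplexEnergyTable, ResidueKey, load_table1_fixture
from parpscreen.structure import Atom, Structure


@pytest.fixture(scope="session")
def table1_panel():
    return load_table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20231024)


def make_atom(
    serial=1,
    name="CA",
    element="C",
    residue_name="ALA",
    chain="A",
    residue_number=1,
    coordinates=(0.0, 0.0, 0.0),
    b_factor=10.0,
    is_hetero=False,
    insertion_code="",
):
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        chain=chain,
        residue_number=residue_number,
        coordinates=np.array(coordinates, dtype=float),
        b_factor=b_factor,
        is_hetero=is_hetero,
        insertion_code=insertion_code,
    )


@pytest.fixture
def random_structure(rng):
    """20 residues x 3 atoms at random positions, plus one hetero residue."""
    atoms = []
    serial = 1
    for resnum in range(1, 21):
        for name in ("N", "CA", "C"):
            atoms.append(
                make_atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_number=resnum,
                    coordinates=rng.uniform(-20, 20, 3).round(3),
                    b_factor=round(float(rng.uniform(5, 60)), 2),
                )
            )
            serial += 1
    atoms.append(
        make_atom(
            serial=serial,
            name="C1",
            element="C",
            residue_name="LIG",
            chain="A",
            residue_number=100,
            coordinates=(0.0, 0.0, 0.0),
            is_hetero=True,
        )
    )
    return Structure(id="toy", atoms=atoms)


def make_energy_table(complex_id, entries, ligand_id="LIG", total_score=None):
    """entries: iterable of (chain, resnum, resname, energy)."""
    return ComplexEnergyTable(
        complex_id=complex_id,
        ligand_id=ligand_id,
        entries={
            ResidueKey(c, n, r.upper()): e for c, n, r, e in entries
        },
        total_score=total_score,
    )
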