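import numpy as np
import pytest

from pocketgauge.structure_io import Atom, Residue, Structure
from pocketgauge.synthetic_data import (
    Motion,
    PlantedContact,
    ToySpec,
    TrajSpec,
    make_toy_pocket,
    make_toy_protein,
    make_toy_trajectory,
)


@pytest.fixture(scope="session")
def displaced_toy():
    """3-domain toy: D2 rigidly rotated+translated, D3 loses 31.8% in the reference."""
    spec = ToySpec(
        n_domains=3,
        residues_per_domain=12,
        transforms=[
            ((0, 0, 1), 0.0, (0, 0, 0)),
            ((0, 1, 0), 30.0, (6.0, 0, 0)),
            ((0, 0, 1), 0.0, (0, 0, 0)),
        ],
        missing_fractions=[0.0, 0.0, 0.25],
        confidence_means=[85.0, 72.0, 91.0],
        seed=11,
    )
    return make_toy_protein(spec)


@pytest.fixture(scope="session")
def clean_toy():
    """Identity toy: no transforms, no noise, no deletions."""
    return make_toy_protein(ToySpec(n_domains=2, residues_per_domain=10, seed=5))


@pytest.fixture(scope="session")
def pocket_structure():
    """Key residues at planted Cα distances with an Arg–Glu salt bridge at 3.0 Å."""
    return make_toy_pocket(
        {(228, 578): 12.7, (228, 629): 10.0, (578, 629): 6.0},
        seed=3,
        planted_salt_bridge=(578, 629, 3.0),
    )


@pytest.fixture()
def ligand_complex():
    """20-residue helix plus a 4-atom HET ligand 30 Å away."""
    model, _, _ = make_toy_protein(ToySpec(n_domains=1, residues_per_domain=20, seed=3))
    lig = Residue(
        chain_id="B",
        number=1,
        icode="",
        name="LIG",
        het=True,
        atoms=[
            Atom(name=f"C{i + 1}", element="C", coords=np.array([30.0 + i, 0.0, 0.0]))
            for i in range(4)
        ],
    )
    return Structure(id="complex", chains={"A": model.chains["A"], "B": [lig]})


@pytest.fixture()
def planted_trajectory(ligand_complex):
    """10 frames: ligand drifts 0.1 Å/frame; one contact present in 6 of 10 frames."""
    spec = TrajSpec(
        base=ligand_complex,
        n_frames=10,
        motions=[Motion(selection="ligand", kind="drift", vector=(0.1, 0.0, 0.0))],
        contacts=[PlantedContact(donor=("A", 5, "N"), acceptor=("A", 15, "O"), fraction=0.6)],
        seed=4,
    )
    return make_toy_trajectory(spec)
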