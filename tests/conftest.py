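import numpy as np
import pytest

from contactmodes.structure import Atom, Frame, StructureModel, TrajectoryEnsemble


def make_bead_structure(residue_atom_counts, rng=None, spread=1.0):
    """Random multi-atom residues scattered in a box; for oracle tests."""
    rng = rng or np.random.default_rng(0)
    atoms, coords = [], []
    aid = 1
    for r, n_atoms in enumerate(residue_atom_counts):
        center = rng.uniform(0.0, 30.0, size=3)
        for a in range(n_atoms):
            atoms.append(Atom(atom_id=aid, atom_name="CA" if a == 0 else f"C{a}",
                              element="C", residue_index=r, residue_name="BEA",
                              chain_id="A"))
            coords.append(center + rng.normal(0.0, spread, size=3))
            aid += 1
    return StructureModel(atoms=atoms, reference_coordinates=np.array(coords))


def two_atom_structure(distance):
    """Two single-atom residues the given distance apart along x."""
    atoms = [Atom(1, "CA", "C", 0, "BEA", "A"), Atom(2, "CA", "C", 1, "BEA", "A")]
    coords = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    return StructureModel(atoms=atoms, reference_coordinates=coords)


def make_trajectory(structure, coord_list, box=None, dt=1.2):
    frames = [Frame(coordinates=c, box=box, time=dt * (k + 1))
              for k, c in enumerate(coord_list)]
    return TrajectoryEnsemble(structure=structure, frames=frames)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
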