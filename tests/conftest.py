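import numpy as np
import pytest

from conftors.synthetic import ToyTransporterParams, make_toy_transporter


@pytest.fixture(scope="session")
def toy():
    """Default toy transporter: (structure, annotation, membrane, ground truth)."""
    return make_toy_transporter(ToyTransporterParams(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_rigid(rng):
    """A uniformly random proper rotation and a translation within +/- 50 A."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-50, 50, size=3)
    return rot, trans


def transform_structure(structure, rot, trans):
    """Rigidly transform every atom (protein and HETATM) of every model."""
    from conftors.structure_io import AtomRecord, Model, Structure

    models = []
    for m in structure.models:
        def moved(atoms):
            return [
                AtomRecord(a.chain_id, a.residue_number, a.insertion_code,
                           a.residue_name, a.atom_name, rot @ a.position + trans)
                for a in atoms
            ]
        models.append(Model(moved(m.atoms), moved(m.het_atoms)))
    return Structure(identifier=structure.identifier + "_moved", models=models)
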