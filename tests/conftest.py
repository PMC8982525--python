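import numpy as np
import pytest

from phoreqsar import descriptors as D
from phoreqsar.pharmacophore import bundled_models


def embedded(smiles: str, mol_id: str, seed: int = 7) -> D.MoleculeRecord:
    """Record with one RDKit-embedded 3D conformer."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    return D.from_rdkit(mol, mol_id)


@pytest.fixture(scope="session")
def water():
    rec = D.from_smiles("O", "water")
    rec.conformers.append(
        D.Conformer(
            np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]])
        )
    )
    return rec


@pytest.fixture(scope="session")
def benzene():
    return embedded("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def ethane():
    return embedded("CC", "ethane")


@pytest.fixture(scope="session")
def models():
    return {m.name: m for m in bundled_models()}


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
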