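import numpy as np
import pytest

from pocketrepo import fixtures, reposition, structio


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_pocket():
    """A 13-residue toy pocket with its backing structure."""
    return fixtures.make_toy_pocket(fixtures.FixtureSpec(seed=11, n_residues=13))


@pytest.fixture
def toy_complex(rng):
    """A toy structure with a 6-atom ligand sitting in its cavity."""
    pocket, structure = fixtures.make_toy_pocket(
        fixtures.FixtureSpec(seed=7, n_residues=12)
    )
    ligand = fixtures.make_toy_ligand(rng, n_atoms=6, center=np.zeros(3), spread=1.5)
    return structure, ligand, pocket


@pytest.fixture
def toy_pose(toy_complex):
    structure, ligand, _ = toy_complex
    return reposition.DrugPose(drug=ligand, source_target_id=structure.id, via="test")


def random_rotation(rng):
    """A uniform random proper rotation matrix."""
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


@pytest.fixture
def pdb_text_3ala():
    """Minimal PDB: 3 ALA residues, one 5-atom ligand, one water."""
    lines = []
    serial = 1
    y = 0.0
    for i in range(1, 4):
        for name, x in (("N", 0.0), ("CA", 1.5), ("C", 2.9), ("O", 3.8)):
            el = name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{0.0:8.3f}{1.00:6.2f}{20.0:6.2f}          {el:>2s}"
            )
            serial += 1
        y += 3.0
    for k, name in enumerate(["C1", "C2", "C3", "O1", "N1"]):
        el = name[0]
        lines.append(
            f"HETATM{serial:5d} {name:^4s} LIG A 100    "
            f"{5.0 + k:8.3f}{1.0:8.3f}{1.0:8.3f}{1.00:6.2f}{20.0:6.2f}          {el:>2s}"
        )
        serial += 1
    lines.append(
        f"HETATM{serial:5d}  O   HOH A 200    "
        f"{9.0:8.3f}{9.0:8.3f}{9.0:8.3f}{1.00:6.2f}{20.0:6.2f}           O"
    )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_file_3ala(tmp_path, pdb_text_3ala):
    path = tmp_path / "toy3ala.pdb"
    path.write_text(pdb_text_3ala)
    return path
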