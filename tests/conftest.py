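"""Shared fixtures: tiny inline structure files and small synthetic datasets."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import sfprobe as sp

# A minimal 1-residue PDB (3 atoms of ALA).
PDB_ALA = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""

# Two GLY residues plus a water; the water must be stripped on read.
PDB_GLY_WATER = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       4.000   0.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       5.458   0.000   0.000  1.00  0.00           C
HETATM    5  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
END
"""

# Ethanol as a Tripos MOL2 file (same molecule as an RDKit-written SDF);
# explicit hydrogens as in real MOL2 files.
MOL2_ETHANOL = """\
@<TRIPOS>MOLECULE
ethanol
 9 8 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
      1 C1          0.0000    0.0000    0.0000 C.3
      2 C2          1.5200    0.0000    0.0000 C.3
      3 O1          2.0500    1.3500    0.0000 O.3
      4 H1          3.0200    1.3300    0.0000 H
      5 H2         -0.3900    0.5100    0.8800 H
      6 H3         -0.3900    0.5100   -0.8800 H
      7 H4         -0.3900   -1.0200    0.0000 H
      8 H5          1.9100   -0.5100    0.8800 H
      9 H6          1.9100   -0.5100   -0.8800 H
@<TRIPOS>BOND
     1    1    2 1
     2    2    3 1
     3    3    4 1
     4    1    5 1
     5    1    6 1
     6    1    7 1
     7    2    8 1
     8    2    9 1
"""


@pytest.fixture
def ala_pdb(tmp_path):
    p = tmp_path / "ala.pdb"
    p.write_text(PDB_ALA)
    return p


@pytest.fixture
def gly_water_pdb(tmp_path):
    p = tmp_path / "glyw.pdb"
    p.write_text(PDB_GLY_WATER)
    return p


@pytest.fixture
def ethanol_sdf(tmp_path):
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles("CCO")
    AllChem.Compute2DCoords(mol)
    p = tmp_path / "ethanol.sdf"
    w = Chem.SDWriter(str(p))
    w.write(mol)
    w.close()
    return p


@pytest.fixture
def ethanol_mol2(tmp_path):
    p = tmp_path / "ethanol.mol2"
    p.write_text(MOL2_ETHANOL)
    return p


@pytest.fixture(scope="session")
def small_library():
    ligands, effects, _ = sp.generate_ligand_library(10, seed=7)
    return ligands, effects


@pytest.fixture(scope="session")
def ligand_signal_records():
    """300 complexes, signal carried by ligand identity only."""
    cfg = sp.GeneratorConfig(n_complexes=300, alpha_ligand=1.0, beta_pocket=0.0, seed=3)
    records, gt = sp.generate_records(cfg)
    return records, gt


@pytest.fixture(scope="session")
def additive_records():
    """250 complexes with additive ligand + pocket signal."""
    cfg = sp.GeneratorConfig(n_complexes=250, alpha_ligand=1.0, beta_pocket=1.0, seed=5)
    records, gt = sp.generate_records(cfg)
    return records, gt


@pytest.fixture(scope="session")
def quick_train_config():
    return sp.TrainConfig(seed=0, search_budget=1)


def fake_record(cid, inchikey, pk, code="", year=None):
    """Duck-typed record for split-construction tests (splits only read
    complex_id, ligand.inchikey, ligand.code, label.pk and year)."""
    return SimpleNamespace(
        complex_id=cid,
        ligand=SimpleNamespace(inchikey=inchikey, code=code),
        label=SimpleNamespace(pk=float(pk)),
        year=year,
    )


def random_pocket_fixture(rng, n_res=12):
    """A random small pocket + ligand pair for geometry tests."""
    comp = np.zeros(20, dtype=int)
    for t in rng.choice(20, size=4, replace=False):
        comp[t] = rng.integers(1, n_res // 3 + 1)
    ligands, _, _ = sp.generate_ligand_library(1, seed=int(rng.integers(0, 2**20)))
    lig = ligands[0]
    prot = sp.generate_pocket(comp, lig.coords, seed=int(rng.integers(0, 2**20)))
    return prot, lig
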