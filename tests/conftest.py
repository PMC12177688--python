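import numpy as np
import pytest

from pocketflim.pocket import Pocket
from pocketflim.structure_io import Atom, Structure


def make_atom(xyz, name="CA", element="C", resname="ALA", resid=("A", 1, ""),
              het=False, occupancy=1.0):
    return Atom(element=element, name=name, coords=tuple(np.asarray(xyz, dtype=float)),
                residue_name=resname, residue_id=resid, is_hetero=het,
                occupancy=occupancy)


def make_structure(atoms, entry_id="TEST", ligand_selector=None, n_models=1):
    """Single- or replicated-model structure from a flat atom list."""
    models = list(range(1, n_models + 1))
    return Structure(entry_id=entry_id, models=models,
                     atoms={m: list(atoms) for m in models},
                     ligand_selector=ligand_selector)


def make_pocket(atoms, cutoff=5.0, model=1):
    """Pocket built directly from its member atoms (heavy atoms assumed)."""
    residues = sorted({(a.residue_id, a.residue_name) for a in atoms})
    return Pocket(residues=list(residues), atoms=list(atoms), cutoff=cutoff,
                  model_index=model)


@pytest.fixture
def toy_shell_structure():
    """Ligand at the origin plus 12 single-atom residues at graded distances
    3.1 ... 8.6 A, half inside and half outside the 5 A pocket cutoff (no
    residue sits exactly on the boundary)."""
    atoms = [make_atom((0, 0, 0), name="C1", element="C", resname="LIG",
                       resid=("L", 900, ""), het=True)]
    rng = np.random.default_rng(42)
    for i, r in enumerate(np.linspace(3.1, 8.6, 12)):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        atoms.append(make_atom(r * u, name="CA", resname="GLY",
                               resid=("A", i + 1, "")))
    return make_structure(atoms, ligand_selector="LIG")


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
HETATM    3  C1  LIG A   2       0.000   0.000   0.000  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       1.100   2.100   3.100  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.600   2.100   3.100  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CB AALA A   1       0.000   2.000   0.000  0.50  0.00           C
ATOM      4  CB BALA A   1       0.000   3.000   0.000  0.50  0.00           C
END
"""
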